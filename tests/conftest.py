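"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Dict, Tuple

import pytest

import doublesub as ds
from doublesub.parsimony import CODING, TripletAlignment


@pytest.fixture(scope="session")
def catalogue():
    return ds.enumerate_combinations()


@pytest.fixture(scope="session")
def main_catalogue():
    return [
        c
        for c in ds.enumerate_combinations(include_excluded=False)
        if c.label in ("SS", "SN", "NS", "NN")
    ]


def make_triplet(
    out_seq: str,
    in1_seq: str,
    in2_seq: str,
    gene_id: str = "g",
    kind: str = CODING,
) -> TripletAlignment:
    return TripletAlignment(
        gene_id=gene_id,
        ids=("out", "in1", "in2"),
        seqs=(out_seq, in1_seq, in2_seq),
        outgroup_id="out",
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Brute-force column-by-column recount, independent of the vectorised tally.
# ---------------------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_tally(alignments) -> Dict[str, Dict[Tuple[str, str], int]]:
    """Plain-Python parsimony recount over every codon column.

    Returns per-kind counts: singles/doubles/triples keyed by
    (ancestral, derived) codon, and anc keyed by ancestral codon with 2
    opportunities per resolved column.  Mirrors the counting rules from
    first principles: a column is resolved when the outgroup codon equals
    at least one ingroup codon, gap/ambiguity columns are skipped, and
    (for coding data) columns whose ancestral codon is a stop are skipped.
    """
    counts = {"singles": {}, "doubles": {}, "triples": {}, "anc": {}}
    for aln in alignments:
        out, in1, in2 = aln.ordered_seqs()
        for k in range(len(out) // 3):
            codons = [s[3 * k : 3 * k + 3].upper() for s in (out, in1, in2)]
            if any(set(c) - set("ACGT") for c in codons):
                continue
            o, i1, i2 = codons
            if o == i1 == i2:
                anc, der = o, None
            elif o == i1:
                anc, der = o, i2
            elif o == i2:
                anc, der = o, i1
            else:
                continue
            if aln.kind == CODING and anc in STOPS:
                continue
            counts["anc"][anc] = counts["anc"].get(anc, 0) + 2
            if der is None:
                continue
            ndiff = sum(a != b for a, b in zip(anc, der))
            kind = {1: "singles", 2: "doubles", 3: "triples"}[ndiff]
            counts[kind][(anc, der)] = counts[kind].get((anc, der), 0) + 1
    return counts


def tally_as_dicts(result) -> Dict[str, Dict[Tuple[str, str], int]]:
    """Convert a TallyResult's matrices into the oracle's dict shape."""
    import numpy as np

    from doublesub.genetic_code import index_to_codon

    out = {"singles": {}, "doubles": {}, "triples": {}, "anc": {}}
    for name, mat in (
        ("singles", result.singles),
        ("doubles", result.doubles),
        ("triples", result.triples),
    ):
        for ai, di in zip(*np.nonzero(mat)):
            out[name][(index_to_codon(int(ai)), index_to_codon(int(di)))] = int(
                mat[ai, di]
            )
    for ai in np.nonzero(result.anc_counts)[0]:
        out["anc"][index_to_codon(int(ai))] = int(result.anc_counts[ai])
    return out
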