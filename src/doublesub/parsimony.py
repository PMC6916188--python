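"""Parsimony inference of substitutions from genome triplets.

A triplet consists of two closely related ingroup genomes and one outgroup.
For a codon column, the ancestral state of the two ingroups is inferable by
parsimony only when the outgroup codon is identical to at least one ingroup
codon; the differing ingroup then carries the inferred substitution(s) on
its terminal branch.  Columns where the outgroup matches neither ingroup,
or where both ingroups share a state that differs from the outgroup (a
change on the outgroup lineage), are uninformative and excluded.

Counting conventions
--------------------
* ``b``  -- instances of a specific double substitution (ancestral and
  derived codon differ at exactly two positions);
* ``a1``/``a2`` -- instances of the two single-substitution intermediate
  steps of that double, ordered 5'-most changed position first;
* ``ANC`` -- ancestral-state opportunities.  Every parsimony-resolved codon
  column contributes 2 to the ANC of its ancestral codon, one per ingroup
  lineage, so ``count/ANC`` is a per-lineage frequency.

Codons differing at all three positions are tallied for the dataset
composition report but never enter the double-fraction statistic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import genetic_code as gc
from .genetic_code import (
    BASE_INDEX,
    NDIFF_TABLE,
    STOP_TABLE,
    SYN_TABLE,
    DoubleCombination,
    index_to_codon,
)

CODING = "coding"
INTERGENIC = "intergenic"

# Base encoding for sequences: A,C,G,T -> 0..3, anything else -> 4 (invalid).
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class TripletAlignmentError(ValueError):
    """Malformed triplet alignment input."""


@dataclass
class TripletAlignment:
    """Three aligned sequences with a designated outgroup."""

    gene_id: str
    ids: Tuple[str, str, str]
    seqs: Tuple[str, str, str]
    outgroup_id: str
    kind: str = CODING

    def __post_init__(self) -> None:
        if len(self.ids) != 3 or len(self.seqs) != 3:
            raise TripletAlignmentError(
                f"{self.gene_id}: a triplet needs exactly 3 records"
            )
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise TripletAlignmentError(
                f"{self.gene_id}: unequal aligned lengths {sorted(lengths)}"
            )
        if self.outgroup_id not in self.ids:
            raise TripletAlignmentError(
                f"{self.gene_id}: outgroup {self.outgroup_id!r} not among records"
            )
        if self.kind == CODING and len(self.seqs[0]) % 3 != 0:
            raise TripletAlignmentError(
                f"{self.gene_id}: coding alignment length not divisible by 3"
            )
        allowed = set("ACGTacgt-NRYSWKMBDHVn")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - allowed
            if bad:
                raise TripletAlignmentError(
                    f"{self.gene_id}/{sid}: non-IUPAC characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def outgroup_index(self) -> int:
        return self.ids.index(self.outgroup_id)

    def ordered_seqs(self) -> Tuple[str, str, str]:
        """Sequences reordered as (outgroup, ingroup1, ingroup2)."""
        oi = self.outgroup_index
        ingroups = [k for k in range(3) if k != oi]
        return self.seqs[oi], self.seqs[ingroups[0]], self.seqs[ingroups[1]]

    def encoded(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        out, in1, in2 = self.ordered_seqs()
        return (
            _ENCODE[np.frombuffer(out.encode(), dtype=np.uint8)],
            _ENCODE[np.frombuffer(in1.encode(), dtype=np.uint8)],
            _ENCODE[np.frombuffer(in2.encode(), dtype=np.uint8)],
        )


def read_triplet_fasta(
    path, outgroup_id: str, gene_id: Optional[str] = None, kind: str = CODING
) -> TripletAlignment:
    """Read a 3-record aligned FASTA into a validated TripletAlignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise TripletAlignmentError(
            f"{path}: expected 3 records, found {len(records)}"
        )
    if gene_id is None:
        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return TripletAlignment(
        gene_id=gene_id,
        ids=tuple(r.id for r in records),  # type: ignore[arg-type]
        seqs=tuple(str(r.seq).upper() for r in records),  # type: ignore[arg-type]
        outgroup_id=outgroup_id,
        kind=kind,
    )


def read_manifest(path) -> List[TripletAlignment]:
    """Load alignments listed in a manifest TSV.

    Columns: ``gene_id``, ``path`` (relative to the manifest), ``outgroup_id``
    and optionally ``kind`` (coding | intergenic).
    """
    manifest = pd.read_csv(path, sep="\t")
    base = os.path.dirname(os.path.abspath(str(path)))
    out = []
    for row in manifest.itertuples(index=False):
        fasta = row.path
        if not os.path.isabs(fasta):
            fasta = os.path.join(base, fasta)
        kind = getattr(row, "kind", CODING)
        out.append(
            read_triplet_fasta(fasta, row.outgroup_id, gene_id=row.gene_id, kind=kind)
        )
    return out


# ---------------------------------------------------------------------------
# Column-level parsimony
# ---------------------------------------------------------------------------

NO_EVENT = "no_event"
UNINFORMATIVE = "uninformative"
SKIPPED = "skipped"


@dataclass(frozen=True)
class EventRecord:
    gene_id: str
    codon_index: int
    ancestral: str
    derived: str
    branch: int  # 1 or 2, the ingroup carrying the change
    n_diff: int

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("event requires ancestral != derived")


def infer_codon_event(
    out_codon: str, in1_codon: str, in2_codon: str, gene_id: str = "", codon_index: int = 0
):
    """Parsimony call for one codon column.

    Returns an :class:`EventRecord`, or one of the markers ``NO_EVENT``,
    ``UNINFORMATIVE`` (outgroup matches neither ingroup, or the change maps
    to the outgroup lineage) and ``SKIPPED`` (gap/ambiguity present).
    """
    for c in (out_codon, in1_codon, in2_codon):
        if len(c) != 3 or any(b not in BASE_INDEX for b in c.upper()):
            return SKIPPED
    out_codon, in1_codon, in2_codon = (
        out_codon.upper(),
        in1_codon.upper(),
        in2_codon.upper(),
    )
    if out_codon == in1_codon == in2_codon:
        return NO_EVENT
    if out_codon == in1_codon:
        anc, der, branch = out_codon, in2_codon, 2
    elif out_codon == in2_codon:
        anc, der, branch = out_codon, in1_codon, 1
    else:
        return UNINFORMATIVE
    return EventRecord(
        gene_id=gene_id,
        codon_index=codon_index,
        ancestral=anc,
        derived=der,
        branch=branch,
        n_diff=len(gc.differing_positions(anc, der)),
    )


# ---------------------------------------------------------------------------
# Vectorised per-gene column resolution
# ---------------------------------------------------------------------------


def _codon_indices(arr: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(codon index array, validity mask) for an encoded base array."""
    n = arr.size - arr.size % 3
    tri = arr[:n].reshape(-1, 3)
    valid = (tri < 4).all(axis=1)
    idx = tri[:, 0].astype(np.int32) * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[~valid] = -1
    return idx, valid


@dataclass
class ResolvedColumns:
    """Parsimony resolution of every codon column of one alignment.

    ``anc`` holds the inferred ancestral codon index for resolved columns
    and -1 elsewhere; ``derived``/``branch`` are set only where an event
    was inferred (branch in {1, 2}).
    """

    anc: np.ndarray
    derived: np.ndarray
    branch: np.ndarray
    resolved: np.ndarray  # ancestral known (no-event or event column)
    event: np.ndarray
    skipped: np.ndarray
    uninformative: np.ndarray


def resolve_columns(aln: TripletAlignment, skip_stop_ancestor: bool = True) -> ResolvedColumns:
    out, in1, in2 = aln.encoded()
    c_out, v_out = _codon_indices(out)
    c_in1, v_in1 = _codon_indices(in1)
    c_in2, v_in2 = _codon_indices(in2)
    valid = v_out & v_in1 & v_in2

    anc = np.full(c_out.shape, -1, dtype=np.int32)
    derived = np.full(c_out.shape, -1, dtype=np.int32)
    branch = np.zeros(c_out.shape, dtype=np.int8)

    eq01 = c_out == c_in1
    eq02 = c_out == c_in2
    all_eq = valid & eq01 & eq02
    ev2 = valid & eq01 & ~eq02
    ev1 = valid & eq02 & ~eq01
    uninformative = valid & ~eq01 & ~eq02

    anc[all_eq | ev1 | ev2] = c_out[all_eq | ev1 | ev2]
    derived[ev1] = c_in1[ev1]
    derived[ev2] = c_in2[ev2]
    branch[ev1] = 1
    branch[ev2] = 2

    resolved = all_eq | ev1 | ev2
    if skip_stop_ancestor and aln.kind == CODING:
        stop_anc = resolved & STOP_TABLE[np.clip(anc, 0, 63)] & (anc >= 0)
        resolved &= ~stop_anc
        uninformative |= stop_anc
    event = resolved & (branch > 0)
    return ResolvedColumns(
        anc=anc,
        derived=derived,
        branch=branch,
        resolved=resolved,
        event=event,
        skipped=~valid,
        uninformative=uninformative,
    )


# ---------------------------------------------------------------------------
# Tallying
# ---------------------------------------------------------------------------

# Nei-Gojobori style synonymous site fraction per codon: over the 9 single-
# base variants, count the synonymous ones (paths to stop codons count as
# non-synonymous opportunities).
def _site_fractions() -> Tuple[np.ndarray, np.ndarray]:
    syn_sites = np.zeros(64)
    for i in range(64):
        if STOP_TABLE[i]:
            continue
        codon = index_to_codon(i)
        syn = 0
        for pos in range(3):
            for b in gc.BASES:
                if b == codon[pos]:
                    continue
                var = codon[:pos] + b + codon[pos + 1 :]
                if gc.synonymous(codon, var):
                    syn += 1
        syn_sites[i] = 3.0 * syn / 9.0
    return syn_sites, 3.0 - syn_sites


SYN_SITES_TABLE, NONSYN_SITES_TABLE = _site_fractions()


@dataclass(frozen=True)
class CountsRecord:
    """Counts for one double combination: b plus its two single steps."""

    ancestral: str
    final: str
    a1: int
    a2: int
    b: int
    anc_count: int

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.b, self.anc_count) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a1 + self.a2 + self.b


@dataclass
class GeneCounts:
    """Per-gene single-substitution census for dN/dS."""

    gene_id: str
    n_events: int
    s_events: int
    n_sites: float
    s_sites: float


@dataclass
class TallyResult:
    """Aggregated substitution tallies over a collection of alignments.

    ``singles``/``doubles`` are 64x64 matrices indexed by (ancestral,
    derived) codon index; ``anc_counts`` is the per-codon ANC vector
    (2 opportunities per resolved column).
    """

    singles: np.ndarray
    doubles: np.ndarray
    triples: np.ndarray
    anc_counts: np.ndarray
    gene_counts: List[GeneCounts] = field(default_factory=list)
    events: List[EventRecord] = field(default_factory=list)
    n_columns: int = 0
    n_resolved: int = 0
    n_skipped: int = 0
    n_uninformative: int = 0

    @classmethod
    def empty(cls) -> "TallyResult":
        return cls(
            singles=np.zeros((64, 64), dtype=np.int64),
            doubles=np.zeros((64, 64), dtype=np.int64),
            triples=np.zeros((64, 64), dtype=np.int64),
            anc_counts=np.zeros(64, dtype=np.int64),
        )

    def counts_record(self, combo: DoubleCombination) -> CountsRecord:
        ai = gc.codon_to_index(combo.ancestral)
        fi = gc.codon_to_index(combo.final)
        i1 = gc.codon_to_index(combo.paths[0].intermediate)
        i2 = gc.codon_to_index(combo.paths[1].intermediate)
        return CountsRecord(
            ancestral=combo.ancestral,
            final=combo.final,
            a1=int(self.singles[ai, i1]),
            a2=int(self.singles[ai, i2]),
            b=int(self.doubles[ai, fi]),
            anc_count=int(self.anc_counts[ai]),
        )

    def composition(self) -> Dict[str, int]:
        return {
            "columns": self.n_columns,
            "resolved": self.n_resolved,
            "single": int(self.singles.sum()),
            "double": int(self.doubles.sum()),
            "triple": int(self.triples.sum()),
            "skipped": self.n_skipped,
            "uninformative": self.n_uninformative,
        }


def tally(
    alignments: Iterable[TripletAlignment],
    collect_events: bool = False,
) -> TallyResult:
    """Tally single/double/triple substitutions and ANC over alignments.

    Also accumulates per-gene N/S event and site counts from single
    substitutions, the inputs to the fast/slow gene split.
    """
    res = TallyResult.empty()
    for aln in alignments:
        cols = resolve_columns(aln)
        res.n_columns += cols.anc.size
        res.n_resolved += int(cols.resolved.sum())
        res.n_skipped += int(cols.skipped.sum())
        res.n_uninformative += int(cols.uninformative.sum())

        anc_res = cols.anc[cols.resolved]
        if anc_res.size:
            res.anc_counts += 2 * np.bincount(anc_res, minlength=64)

        ev = cols.event
        if not ev.any():
            if aln.kind == CODING:
                res.gene_counts.append(
                    _gene_counts(aln.gene_id, cols, np.zeros(0, np.int32), np.zeros(0, np.int32))
                )
            continue
        anc_ev = cols.anc[ev]
        der_ev = cols.derived[ev]
        nd = NDIFF_TABLE[anc_ev, der_ev]
        pair = anc_ev * 64 + der_ev
        for k, mat in ((1, res.singles), (2, res.doubles), (3, res.triples)):
            sel = pair[nd == k]
            if sel.size:
                mat += np.bincount(sel, minlength=4096).reshape(64, 64)

        if aln.kind == CODING:
            res.gene_counts.append(_gene_counts(aln.gene_id, cols, anc_ev, der_ev))

        if collect_events:
            idx = np.flatnonzero(ev)
            for j in idx:
                res.events.append(
                    EventRecord(
                        gene_id=aln.gene_id,
                        codon_index=int(j),
                        ancestral=index_to_codon(int(cols.anc[j])),
                        derived=index_to_codon(int(cols.derived[j])),
                        branch=int(cols.branch[j]),
                        n_diff=int(NDIFF_TABLE[cols.anc[j], cols.derived[j]]),
                    )
                )
    return res


def _gene_counts(
    gene_id: str, cols: ResolvedColumns, anc_ev: np.ndarray, der_ev: np.ndarray
) -> GeneCounts:
    anc_res = cols.anc[cols.resolved]
    s_sites = float(SYN_SITES_TABLE[anc_res].sum()) if anc_res.size else 0.0
    n_sites = float(NONSYN_SITES_TABLE[anc_res].sum()) if anc_res.size else 0.0
    if anc_ev.size:
        single = NDIFF_TABLE[anc_ev, der_ev] == 1
        syn = SYN_TABLE[anc_ev[single], der_ev[single]]
        s_events = int(syn.sum())
        n_events = int((~syn).sum())
    else:
        s_events = n_events = 0
    return GeneCounts(gene_id, n_events, s_events, n_sites, s_sites)


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------


def ledger_dataframe(result: TallyResult, combinations: Sequence[DoubleCombination]) -> pd.DataFrame:
    rows = []
    for combo in combinations:
        rec = result.counts_record(combo)
        rows.append(
            {
                "ancestral": rec.ancestral,
                "final": rec.final,
                "label": combo.label,
                "a1": rec.a1,
                "a2": rec.a2,
                "b": rec.b,
                "ANC": rec.anc_count,
            }
        )
    return pd.DataFrame(rows)


def gene_rates_dataframe(result: TallyResult) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g.gene_id,
            "n_events": g.n_events,
            "s_events": g.s_events,
            "n_sites": g.n_sites,
            "s_sites": g.s_sites,
        }
        for g in result.gene_counts
    ]
    return pd.DataFrame(rows)
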