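"""Genetic-code combinatorics for within-codon double substitutions.

A double substitution is an ordered pair of codons (ancestral, final)
differing at exactly two positions.  Under the assumption that point
mutations arise one at a time, every such pair can be traversed along two
single-step paths through an intermediate codon.  The synonymy of the two
intermediates and of the final codon relative to the ancestral codon
partitions all double substitutions into classes:

* ``SS`` -- both intermediates synonymous, final synonymous;
* ``SN`` -- at least one intermediate synonymous, final non-synonymous;
* ``NS`` -- one intermediate synonymous, one non-synonymous, final
  synonymous (the second step restores the ancestral amino acid);
* ``NN`` -- both intermediates non-synonymous, final non-synonymous;
* ``SER`` -- both intermediates non-synonymous yet the final codon is
  synonymous; under the standard code this occurs only between the two
  disjoint serine codon series and is handled separately;
* ``EXCLUDED_STOP`` -- at least one intermediate is a stop codon, which
  removes the pair from the analysis.

Pairs whose ancestral or final codon is itself a stop codon are rejected
outright (they are not part of the coding analysis at all).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_SYMBOL = "*"

PURINES = frozenset("AG")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# Classification labels.
SS = "SS"
SN = "SN"
NS = "NS"
NN = "NN"
SER = "SER"
EXCLUDED_STOP = "EXCLUDED_STOP"
CLASS_LABELS = (SS, SN, NS, NN, SER, EXCLUDED_STOP)


class InvalidCodonError(ValueError):
    """Raised for codons outside the {A,C,G,T}^3 alphabet."""


class StopEndpointError(ValueError):
    """Raised when an ancestral or final codon is a stop codon."""


def _build_code(table_id: int = 11) -> Dict[str, str]:
    """Codon -> amino acid (one letter), stops mapped to ``*``.

    NCBI table 11 (bacterial/archaeal/plant plastid) shares the codon
    assignments of the standard code; only start-codon semantics differ,
    which are irrelevant here.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP_SYMBOL
    return code


GENETIC_CODE: Dict[str, str] = _build_code()
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == STOP_SYMBOL)
ALL_CODONS: Tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
SENSE_CODONS: Tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


def codon_to_index(codon: str) -> int:
    """Pack a codon into an integer in ``[0, 64)`` (A=0, C=1, G=2, T=3)."""
    return (
        BASE_INDEX[codon[0]] * 16 + BASE_INDEX[codon[1]] * 4 + BASE_INDEX[codon[2]]
    )


def index_to_codon(idx: int) -> str:
    return BASES[idx // 16] + BASES[(idx // 4) % 4] + BASES[idx % 4]


def _validate(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASE_INDEX for b in codon):
        raise InvalidCodonError(f"not a DNA codon: {codon!r}")


def translate(codon: str) -> str:
    """Translate a codon under the standard code; stops return ``'*'``."""
    _validate(codon)
    return GENETIC_CODE[codon]


def is_stop(codon: str) -> bool:
    _validate(codon)
    return codon in STOP_CODONS


def synonymous(codon_a: str, codon_b: str) -> bool:
    """True when both codons encode the same amino acid (stops never count)."""
    aa, ab = translate(codon_a), translate(codon_b)
    return aa == ab and aa != STOP_SYMBOL


def is_transition(base_from: str, base_to: str) -> bool:
    return (base_from, base_to) in _TRANSITIONS


def differing_positions(codon_a: str, codon_b: str) -> Tuple[int, ...]:
    """1-based codon positions at which the two codons differ."""
    return tuple(i + 1 for i in range(3) if codon_a[i] != codon_b[i])


@dataclass(frozen=True)
class SubstitutionPath:
    """One single-step trajectory ancestral -> intermediate -> final."""

    ancestral: str
    intermediate: str
    final: str

    @property
    def step1_synonymous(self) -> bool:
        """Synonymy of the intermediate relative to the ancestral codon."""
        return synonymous(self.ancestral, self.intermediate)

    @property
    def final_synonymous(self) -> bool:
        return synonymous(self.ancestral, self.final)

    @property
    def stop_intermediate(self) -> bool:
        return self.intermediate in STOP_CODONS

    @property
    def intermediate_synonymous_to_final(self) -> bool:
        return synonymous(self.intermediate, self.final)


@dataclass(frozen=True)
class DoubleCombination:
    """A directed codon pair at Hamming distance 2, with both paths.

    ``paths`` is ordered 5'-first: ``paths[0]`` changes the 5'-most
    differing position first (its intermediate carries that change), and
    the tallying convention a1/a2 follows the same order.
    """

    ancestral: str
    final: str
    positions: Tuple[int, int]  # 1-based, ascending
    paths: Tuple[SubstitutionPath, SubstitutionPath]
    label: str
    transitions: Tuple[bool, bool]  # per changed position, 5' first

    @property
    def adjacent(self) -> bool:
        return self.positions in ((1, 2), (2, 3))

    @property
    def changes(self) -> Tuple[Tuple[str, str], Tuple[str, str]]:
        """Ordered (from, to) base changes, 5'-most first."""
        return tuple(
            (self.ancestral[p - 1], self.final[p - 1]) for p in self.positions
        )  # type: ignore[return-value]

    @property
    def amino_acids(self) -> Tuple[str, str, str, str]:
        """(ancestral, intermediate1, intermediate2, final) amino acids."""
        return (
            translate(self.ancestral),
            translate(self.paths[0].intermediate),
            translate(self.paths[1].intermediate),
            translate(self.final),
        )


def intermediates(ancestral: str, final: str) -> Tuple[SubstitutionPath, SubstitutionPath]:
    """The two single-step paths between codons differing at two positions.

    The first path applies the change at the 5'-most differing position
    first.  Raises ``ValueError`` unless the codons differ at exactly two
    positions.
    """
    _validate(ancestral)
    _validate(final)
    diff = differing_positions(ancestral, final)
    if len(diff) != 2:
        raise ValueError(
            f"{ancestral}->{final}: expected 2 differing positions, found {len(diff)}"
        )
    paths = []
    for p in diff:
        inter = list(ancestral)
        inter[p - 1] = final[p - 1]
        paths.append(SubstitutionPath(ancestral, "".join(inter), final))
    return paths[0], paths[1]


def _label_from_paths(
    path1: SubstitutionPath, path2: SubstitutionPath
) -> str:
    if path1.stop_intermediate or path2.stop_intermediate:
        return EXCLUDED_STOP
    s1, s2 = path1.step1_synonymous, path2.step1_synonymous
    final_syn = path1.final_synonymous
    if final_syn:
        if s1 and s2:
            return SS
        if s1 or s2:
            return NS
        return SER
    if s1 or s2:
        return SN
    return NN


def classify(ancestral: str, final: str) -> DoubleCombination:
    """Classify a directed codon pair at Hamming distance 2.

    Stop endpoints raise :class:`StopEndpointError`; a stop *intermediate*
    instead yields the ``EXCLUDED_STOP`` label, mirroring the rule that
    such double substitutions are dropped from the analysis rather than
    being malformed input.
    """
    _validate(ancestral)
    _validate(final)
    if ancestral in STOP_CODONS or final in STOP_CODONS:
        raise StopEndpointError(f"stop codon endpoint in {ancestral}->{final}")
    path1, path2 = intermediates(ancestral, final)
    diff = differing_positions(ancestral, final)
    label = _label_from_paths(path1, path2)
    transitions = tuple(
        is_transition(ancestral[p - 1], final[p - 1]) for p in diff
    )
    return DoubleCombination(
        ancestral=ancestral,
        final=final,
        positions=(diff[0], diff[1]),
        paths=(path1, path2),
        label=label,
        transitions=transitions,  # type: ignore[arg-type]
    )


def enumerate_combinations(include_excluded: bool = True) -> List[DoubleCombination]:
    """All directed sense-codon pairs at Hamming distance 2, classified.

    With ``include_excluded=False`` the ``EXCLUDED_STOP`` combinations are
    dropped.  Pairs with a stop endpoint are never produced.
    """
    out: List[DoubleCombination] = []
    for anc in SENSE_CODONS:
        for fin in SENSE_CODONS:
            if len(differing_positions(anc, fin)) != 2:
                continue
            combo = classify(anc, fin)
            if not include_excluded and combo.label == EXCLUDED_STOP:
                continue
            out.append(combo)
    return out


def class_counts(combinations: Optional[List[DoubleCombination]] = None) -> Dict[str, int]:
    """Number of combinations per class label."""
    combos = enumerate_combinations() if combinations is None else combinations
    counts = {label: 0 for label in CLASS_LABELS}
    for c in combos:
        counts[c.label] += 1
    return counts


def nn_intermediates_synonymous_to_final(
    combinations: Optional[List[DoubleCombination]] = None,
) -> List[DoubleCombination]:
    """The NN subset where both intermediates encode the final amino acid.

    For these the second substitution does not change the amino acid, so
    it is expected to behave neutrally.
    """
    combos = enumerate_combinations() if combinations is None else combinations
    return [
        c
        for c in combos
        if c.label == NN
        and c.paths[0].intermediate_synonymous_to_final
        and c.paths[1].intermediate_synonymous_to_final
    ]


def degeneracy(codon: str) -> Tuple[bool, bool]:
    """(fourfold third position, twofold first position) flags.

    A codon is fourfold-degenerate at the third position when every
    third-position variant is synonymous.  It is twofold-degenerate at the
    first position when exactly one first-position variant is synonymous
    (leucine TTR/CTR and arginine AGR/CGR under the standard code).
    """
    _validate(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"degeneracy undefined for stop codon {codon}")
    third = [codon[:2] + b for b in BASES if b != codon[2]]
    fourfold = all(synonymous(codon, c) for c in third)
    first = [b + codon[1:] for b in BASES if b != codon[0]]
    twofold_first = sum(synonymous(codon, c) for c in first) == 1
    return fourfold, twofold_first


def catalogue_dataframe(
    combinations: Optional[List[DoubleCombination]] = None,
) -> pd.DataFrame:
    """The full combination catalogue as a flat table (TSV-exportable)."""
    combos = enumerate_combinations() if combinations is None else combinations
    rows = []
    for c in combos:
        (f1, t1), (f2, t2) = c.changes
        rows.append(
            {
                "ancestral": c.ancestral,
                "final": c.final,
                "label": c.label,
                "pos1": c.positions[0],
                "pos2": c.positions[1],
                "adjacent": c.adjacent,
                "change1": f"{f1}>{t1}",
                "change2": f"{f2}>{t2}",
                "ts1": c.transitions[0],
                "ts2": c.transitions[1],
                "intermediate1": c.paths[0].intermediate,
                "intermediate2": c.paths[1].intermediate,
                "inter1_syn": c.paths[0].step1_synonymous
                if not c.paths[0].stop_intermediate
                else False,
                "inter2_syn": c.paths[1].step1_synonymous
                if not c.paths[1].stop_intermediate
                else False,
            }
        )
    return pd.DataFrame(rows)


def write_catalogue_tsv(path, combinations: Optional[List[DoubleCombination]] = None) -> None:
    catalogue_dataframe(combinations).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Integer lookup tables used by the vectorised tally and null-model scans.
# ---------------------------------------------------------------------------


def _build_tables():
    n = 64
    aa = np.empty(n, dtype="<U1")
    stop = np.zeros(n, dtype=bool)
    for i in range(n):
        aa[i] = GENETIC_CODE[index_to_codon(i)]
    stop = aa == STOP_SYMBOL
    syn = (aa[:, None] == aa[None, :]) & ~stop[:, None] & ~stop[None, :]
    base = np.empty((n, 3), dtype=np.int8)
    for i in range(n):
        c = index_to_codon(i)
        base[i] = [BASE_INDEX[b] for b in c]
    ndiff = (base[:, None, :] != base[None, :, :]).sum(axis=2).astype(np.int8)
    fourfold3 = np.zeros(n, dtype=bool)
    twofold1 = np.zeros(n, dtype=bool)
    for i, codon in enumerate(ALL_CODONS):
        if codon in STOP_CODONS:
            continue
        f, t = degeneracy(codon)
        fourfold3[i] = f
        twofold1[i] = t
    return aa, stop, syn, base, ndiff, fourfold3, twofold1


(
    AA_TABLE,
    STOP_TABLE,
    SYN_TABLE,
    BASE_TABLE,
    NDIFF_TABLE,
    FOURFOLD3_TABLE,
    TWOFOLD1_TABLE,
) = _build_tables()

PURINE3_TABLE = np.isin(BASE_TABLE[:, 2], [BASE_INDEX["A"], BASE_INDEX["G"]])


def _iter_hamming2_pairs() -> Iterator[Tuple[int, int]]:
    for i in range(64):
        for j in range(64):
            if NDIFF_TABLE[i, j] == 2:
                yield i, j
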