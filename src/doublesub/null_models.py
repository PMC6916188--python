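"""Synonymous null models for double substitutions.

Within-codon double substitutions cannot be compared directly to single
synonymous substitutions because multi-nucleotide mutations inflate the
rate of *adjacent* double changes.  The controls used here are artificial
"pseudo-codons" assembled from positions of two adjacent real codons in
which every change is synonymous by construction:

* ``NM1_23`` -- a constant base at the second position of codon *i*,
  a fourfold-degenerate third position of codon *i*, and a twofold-
  degenerate first position of codon *ii* (adjacent changes, trailing
  context);
* ``NM1_12`` -- the same two degenerate sites, with the constant context
  base taken from the second position of codon *ii* (adjacent changes,
  leading context);
* ``NM2``   -- fourfold-degenerate third positions of codons *i* and
  *ii*, with the first position of codon *ii* as the constant base in
  between (non-adjacent changes).

Codon *i* must be fourfold-degenerate at its third position.  For the NM1
configurations codon *ii* must encode leucine or arginine -- the only
amino acids with a degenerate first codon position -- and carry a purine
at its third position (otherwise the first-position change cannot be
synonymous).  For NM2 both codons must be fourfold-degenerate.

Each within-codon double combination maps onto the null configuration
with the same base changes and the same constant context base, preserving
adjacency: codon changes at positions (2,3) map to NM1_23, (1,2) to
NM1_12 and (1,3) to NM2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .genetic_code import (
    BASES,
    BASE_TABLE,
    FOURFOLD3_TABLE,
    PURINE3_TABLE,
    SYN_TABLE,
    TWOFOLD1_TABLE,
    DoubleCombination,
)
from .parsimony import INTERGENIC, TripletAlignment, TallyResult, resolve_columns, tally

NM1_23 = "NM1_23"
NM1_12 = "NM1_12"
NM2 = "NM2"
CONFIGS = (NM1_23, NM1_12, NM2)

# The unique synonymous first-position alternative base for Leu/Arg codons
# with a degenerate first position; -1 elsewhere.
_SYN_TARGET1 = np.full(64, -1, dtype=np.int8)
for _i in range(64):
    _codon = gc.index_to_codon(_i)
    if _codon in gc.STOP_CODONS or not TWOFOLD1_TABLE[_i]:
        continue
    for _b in BASES:
        if _b != _codon[0] and gc.synonymous(_codon, _b + _codon[1:]):
            _SYN_TARGET1[_i] = gc.BASE_INDEX[_b]


@dataclass(frozen=True)
class NullWindowKey:
    """Identity of a null-model instance.

    ``change1``/``change2`` are ordered (from, to) base pairs, the change
    at the 5'-most pseudo-codon site first; ``constant`` is the unchanged
    context base.
    """

    config: str
    change1: Tuple[str, str]
    change2: Tuple[str, str]
    constant: str


@dataclass(frozen=True)
class NullCountsRecord:
    key: NullWindowKey
    a1: int
    a2: int
    b: int
    anc_count: int

    @property
    def total(self) -> int:
        return self.a1 + self.a2 + self.b


def eligible_window(codon_i: str, codon_ii: str, config: str) -> bool:
    """Whether an ancestral codon pair can host the given null configuration."""
    i = gc.codon_to_index(codon_i.upper())
    ii = gc.codon_to_index(codon_ii.upper())
    if config in (NM1_23, NM1_12):
        return bool(FOURFOLD3_TABLE[i] and TWOFOLD1_TABLE[ii] and PURINE3_TABLE[ii])
    if config == NM2:
        return bool(FOURFOLD3_TABLE[i] and FOURFOLD3_TABLE[ii])
    raise ValueError(f"unknown configuration {config!r}")


# ---------------------------------------------------------------------------
# Scanning coding alignments
# ---------------------------------------------------------------------------


class NullLedger:
    """Accumulates NM1/NM2 window tallies over alignments.

    Internally NM1 windows are keyed by (from1, from2, synonymous target of
    the twofold site, constant base) so that ANC counts only windows in
    which the keyed pair of synonymous changes is actually realisable;
    NM2 windows by (from1, from2, constant base), every third-position
    change being synonymous at a fourfold site.
    """

    def __init__(self) -> None:
        # NM1 configs: state = ((from1*4+from2)*4+to2)*4+const -> 256 states
        self._nm1_anc = {c: np.zeros(256, dtype=np.int64) for c in (NM1_23, NM1_12)}
        self._nm1_singles1 = {c: np.zeros((256, 4), dtype=np.int64) for c in (NM1_23, NM1_12)}
        self._nm1_singles2 = {c: np.zeros(256, dtype=np.int64) for c in (NM1_23, NM1_12)}
        self._nm1_doubles = {c: np.zeros((256, 4), dtype=np.int64) for c in (NM1_23, NM1_12)}
        # NM2: state = (from1*4+from2)*4+const -> 64 states
        self._nm2_anc = np.zeros(64, dtype=np.int64)
        self._nm2_singles1 = np.zeros((64, 4), dtype=np.int64)
        self._nm2_singles2 = np.zeros((64, 4), dtype=np.int64)
        self._nm2_doubles = np.zeros((64, 16), dtype=np.int64)

    # -- scanning ----------------------------------------------------------

    def scan(self, alignments: Iterable[TripletAlignment]) -> "NullLedger":
        for aln in alignments:
            self._scan_one(aln)
        return self

    def _scan_one(self, aln: TripletAlignment) -> None:
        cols = resolve_columns(aln)
        n = cols.anc.size
        if n < 2:
            return
        w = np.arange(n - 1)
        ok = cols.resolved[w] & cols.resolved[w + 1]
        if not ok.any():
            return
        w = w[ok]
        anc_i, anc_ii = cols.anc[w], cols.anc[w + 1]

        # Derived codon per ingroup branch: the event's derived state on the
        # branch that carries it, the ancestral state on the other branch.
        der = {}
        for k in (1, 2):
            di = np.where(cols.branch[w] == k, cols.derived[w], anc_i)
            dii = np.where(cols.branch[w + 1] == k, cols.derived[w + 1], anc_ii)
            der[k] = (di, dii)

        elig_nm1 = FOURFOLD3_TABLE[anc_i] & TWOFOLD1_TABLE[anc_ii] & PURINE3_TABLE[anc_ii]
        elig_nm2 = FOURFOLD3_TABLE[anc_i] & FOURFOLD3_TABLE[anc_ii]

        self._scan_nm1(anc_i, anc_ii, der, elig_nm1)
        self._scan_nm2(anc_i, anc_ii, der, elig_nm2)

    def _scan_nm1(self, anc_i, anc_ii, der, elig) -> None:
        if not elig.any():
            return
        ai, aii = anc_i[elig], anc_ii[elig]
        from1 = BASE_TABLE[ai, 2].astype(np.int64)
        from2 = BASE_TABLE[aii, 0].astype(np.int64)
        to2 = _SYN_TARGET1[aii].astype(np.int64)
        base_state = (from1 * 4 + from2) * 4 + to2
        const = {
            NM1_23: BASE_TABLE[ai, 1].astype(np.int64),
            NM1_12: BASE_TABLE[aii, 1].astype(np.int64),
        }
        for cfg in (NM1_23, NM1_12):
            state = base_state * 4 + const[cfg]
            self._nm1_anc[cfg] += 2 * np.bincount(state, minlength=256)

        for k in (1, 2):
            di, dii = der[k][0][elig], der[k][1][elig]
            diff_i = BASE_TABLE[ai] != BASE_TABLE[di]
            diff_ii = BASE_TABLE[aii] != BASE_TABLE[dii]
            clean = ~diff_i[:, 0] & ~diff_i[:, 1] & ~diff_ii[:, 1] & ~diff_ii[:, 2]
            ch1 = diff_i[:, 2]
            ch2 = diff_ii[:, 0]
            syn1 = ~ch1 | SYN_TABLE[ai, di]
            syn2 = ~ch2 | SYN_TABLE[aii, dii]
            countable = clean & syn1 & syn2
            to1 = BASE_TABLE[di, 2].astype(np.int64)
            dbl = countable & ch1 & ch2
            s1 = countable & ch1 & ~ch2
            s2 = countable & ~ch1 & ch2
            for cfg in (NM1_23, NM1_12):
                state = base_state * 4 + const[cfg]
                if dbl.any():
                    self._nm1_doubles[cfg] += np.bincount(
                        state[dbl] * 4 + to1[dbl], minlength=1024
                    ).reshape(256, 4)
                if s1.any():
                    self._nm1_singles1[cfg] += np.bincount(
                        state[s1] * 4 + to1[s1], minlength=1024
                    ).reshape(256, 4)
                if s2.any():
                    self._nm1_singles2[cfg] += np.bincount(state[s2], minlength=256)

    def _scan_nm2(self, anc_i, anc_ii, der, elig) -> None:
        if not elig.any():
            return
        ai, aii = anc_i[elig], anc_ii[elig]
        from1 = BASE_TABLE[ai, 2].astype(np.int64)
        from2 = BASE_TABLE[aii, 2].astype(np.int64)
        const = BASE_TABLE[aii, 0].astype(np.int64)
        state = (from1 * 4 + from2) * 4 + const
        self._nm2_anc += 2 * np.bincount(state, minlength=64)
        for k in (1, 2):
            di, dii = der[k][0][elig], der[k][1][elig]
            diff_i = BASE_TABLE[ai] != BASE_TABLE[di]
            diff_ii = BASE_TABLE[aii] != BASE_TABLE[dii]
            clean = ~diff_i[:, 0] & ~diff_i[:, 1] & ~diff_ii[:, 0] & ~diff_ii[:, 1]
            ch1 = diff_i[:, 2]
            ch2 = diff_ii[:, 2]
            syn1 = ~ch1 | SYN_TABLE[ai, di]
            syn2 = ~ch2 | SYN_TABLE[aii, dii]
            countable = clean & syn1 & syn2
            to1 = BASE_TABLE[di, 2].astype(np.int64)
            to2 = BASE_TABLE[dii, 2].astype(np.int64)
            dbl = countable & ch1 & ch2
            s1 = countable & ch1 & ~ch2
            s2 = countable & ~ch1 & ch2
            if dbl.any():
                self._nm2_doubles += np.bincount(
                    state[dbl] * 16 + to1[dbl] * 4 + to2[dbl], minlength=1024
                ).reshape(64, 16)
            if s1.any():
                self._nm2_singles1 += np.bincount(
                    state[s1] * 4 + to1[s1], minlength=256
                ).reshape(64, 4)
            if s2.any():
                self._nm2_singles2 += np.bincount(
                    state[s2] * 4 + to2[s2], minlength=256
                ).reshape(64, 4)

    # -- materialisation ---------------------------------------------------

    def records(self) -> Dict[NullWindowKey, NullCountsRecord]:
        out: Dict[NullWindowKey, NullCountsRecord] = {}
        for cfg in (NM1_23, NM1_12):
            anc = self._nm1_anc[cfg]
            for state in np.flatnonzero(anc):
                const = state % 4
                to2 = (state // 4) % 4
                from2 = (state // 16) % 4
                from1 = state // 64
                for to1 in range(4):
                    if to1 == from1:
                        continue
                    key = NullWindowKey(
                        config=cfg,
                        change1=(BASES[from1], BASES[to1]),
                        change2=(BASES[from2], BASES[to2]),
                        constant=BASES[const],
                    )
                    out[key] = NullCountsRecord(
                        key=key,
                        a1=int(self._nm1_singles1[cfg][state, to1]),
                        a2=int(self._nm1_singles2[cfg][state]),
                        b=int(self._nm1_doubles[cfg][state, to1]),
                        anc_count=int(anc[state]),
                    )
        for state in np.flatnonzero(self._nm2_anc):
            const = state % 4
            from2 = (state // 4) % 4
            from1 = state // 16
            for to1 in range(4):
                if to1 == from1:
                    continue
                for to2 in range(4):
                    if to2 == from2:
                        continue
                    key = NullWindowKey(
                        config=NM2,
                        change1=(BASES[from1], BASES[to1]),
                        change2=(BASES[from2], BASES[to2]),
                        constant=BASES[const],
                    )
                    out[key] = NullCountsRecord(
                        key=key,
                        a1=int(self._nm2_singles1[state, to1]),
                        a2=int(self._nm2_singles2[state, to2]),
                        b=int(self._nm2_doubles[state, to1 * 4 + to2]),
                        anc_count=int(self._nm2_anc[state]),
                    )
        return out


def scan_nulls(
    alignments: Iterable[TripletAlignment], configs: Tuple[str, ...] = CONFIGS
) -> Dict[NullWindowKey, NullCountsRecord]:
    """Scan coding alignments and return all null-window count records."""
    ledger = NullLedger().scan(alignments)
    recs = ledger.records()
    return {k: r for k, r in recs.items() if k.config in configs}


def ledger_dataframe(records: Dict[NullWindowKey, NullCountsRecord]) -> pd.DataFrame:
    rows = []
    for key, rec in records.items():
        rows.append(
            {
                "config": key.config,
                "constant": key.constant,
                "change1": f"{key.change1[0]}>{key.change1[1]}",
                "change2": f"{key.change2[0]}>{key.change2[1]}",
                "a1": rec.a1,
                "a2": rec.a2,
                "b": rec.b,
                "ANC": rec.anc_count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Matching codon combinations to null keys
# ---------------------------------------------------------------------------


def _realizable_keys() -> frozenset:
    keys = set()
    for i in range(64):
        if not FOURFOLD3_TABLE[i]:
            continue
        ci = gc.index_to_codon(i)
        from1 = ci[2]
        for to1 in BASES:
            if to1 == from1:
                continue
            # NM1 partner codons
            for ii in range(64):
                if not (TWOFOLD1_TABLE[ii] and PURINE3_TABLE[ii]):
                    continue
                cii = gc.index_to_codon(ii)
                to2 = BASES[_SYN_TARGET1[ii]]
                keys.add((NM1_23, from1, to1, cii[0], to2, ci[1]))
                keys.add((NM1_12, from1, to1, cii[0], to2, cii[1]))
            # NM2 partner codons
            for ii in range(64):
                if not FOURFOLD3_TABLE[ii]:
                    continue
                cii = gc.index_to_codon(ii)
                for to2 in BASES:
                    if to2 == cii[2]:
                        continue
                    keys.add((NM2, from1, to1, cii[2], to2, cii[0]))
    return frozenset(keys)


REALIZABLE_KEYS = _realizable_keys()

_POSITIONS_TO_CONFIG = {(2, 3): NM1_23, (1, 2): NM1_12, (1, 3): NM2}
# Constant context base: the codon position that does not change.
_CONSTANT_POSITION = {(2, 3): 1, (1, 2): 3, (1, 3): 2}


@dataclass(frozen=True)
class MatchedKey:
    key: NullWindowKey
    realizable: bool


def match_key(combination: DoubleCombination) -> MatchedKey:
    """Map a codon double combination to its base-change-equivalent null key.

    The mapping preserves adjacency and copies the ordered base changes and
    the unchanged context base verbatim.  ``realizable`` is False when no
    eligible ancestral window under the standard code can produce the key
    with both changes synonymous (such combinations have no matched null).
    """
    if combination.label in (gc.EXCLUDED_STOP,):
        raise ValueError("cannot match an excluded combination")
    pos = combination.positions
    config = _POSITIONS_TO_CONFIG[pos]
    cpos = _CONSTANT_POSITION[pos]
    anc, fin = combination.ancestral, combination.final
    change1 = (anc[pos[0] - 1], fin[pos[0] - 1])
    change2 = (anc[pos[1] - 1], fin[pos[1] - 1])
    constant = anc[cpos - 1]
    key = NullWindowKey(config=config, change1=change1, change2=change2, constant=constant)
    realizable = (
        config,
        change1[0],
        change1[1],
        change2[0],
        change2[1],
        constant,
    ) in REALIZABLE_KEYS
    return MatchedKey(key=key, realizable=realizable)


# ---------------------------------------------------------------------------
# Non-coding pseudo-codon nulls
# ---------------------------------------------------------------------------


@dataclass
class FrameTally:
    """Substitution tallies for one reading frame of intergenic alignments."""

    frame: int
    result: TallyResult

    def double_records(self) -> List[dict]:
        """Distance-2 pseudo-codon records with adjacency stratification."""
        rows = []
        doubles = self.result.doubles
        singles = self.result.singles
        anc_counts = self.result.anc_counts
        for ai, fi in zip(*np.nonzero(gc.NDIFF_TABLE == 2)):
            if anc_counts[ai] == 0:
                continue
            anc = gc.index_to_codon(int(ai))
            fin = gc.index_to_codon(int(fi))
            diff = gc.differing_positions(anc, fin)
            inter1 = anc[: diff[0] - 1] + fin[diff[0] - 1] + anc[diff[0] :]
            inter2 = anc[: diff[1] - 1] + fin[diff[1] - 1] + anc[diff[1] :]
            rows.append(
                {
                    "frame": self.frame,
                    "ancestral": anc,
                    "final": fin,
                    "adjacent": diff in ((1, 2), (2, 3)),
                    "a1": int(singles[ai, gc.codon_to_index(inter1)]),
                    "a2": int(singles[ai, gc.codon_to_index(inter2)]),
                    "b": int(doubles[ai, fi]),
                    "ANC": int(anc_counts[ai]),
                }
            )
        return rows


def scan_noncoding(alignments: Iterable[TripletAlignment]) -> List[FrameTally]:
    """Tally pseudo-codon substitutions in all 3 frames of intergenic data.

    Base triplets are treated as codons without any synonymy or stop-codon
    constraints; doubles are stratified by the adjacency of the two changed
    positions so they can serve as frame-free null models.
    """
    frames: List[FrameTally] = []
    alns = list(alignments)
    for frame in range(3):
        shifted = []
        for aln in alns:
            if aln.length - frame < 3:
                continue
            shifted.append(
                TripletAlignment(
                    gene_id=f"{aln.gene_id}|frame{frame}",
                    ids=aln.ids,
                    seqs=tuple(s[frame:] for s in aln.seqs),  # type: ignore[arg-type]
                    outgroup_id=aln.outgroup_id,
                    kind=INTERGENIC,
                )
            )
        frames.append(FrameTally(frame=frame, result=tally(shifted)))
    return frames


def noncoding_df_values(
    frames: List[FrameTally], adjacent: bool, min_total: int = 1
) -> List[float]:
    """DF values of intergenic pseudo-codon doubles in one adjacency stratum."""
    values = []
    for ft in frames:
        for row in ft.double_records():
            if row["adjacent"] != adjacent:
                continue
            total = row["a1"] + row["a2"] + row["b"]
            if total >= min_total:
                values.append(row["b"] / total)
    return values
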