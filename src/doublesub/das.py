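"""Amino-acid similarity and the DAS metric.

DAS asks whether the second step of a double substitution moves the
encoded amino acid towards or away from the ancestral one:

    DAS = S(original, final) - mean_i S(original, intermediate_i)

where S is taken from an amino-acid similarity or distance matrix and the
mean runs over the two single-step intermediates.  Synonymous steps use
the matrix diagonal (an amino acid compared to itself), so SS combinations
always score 0 and NS combinations score >= 0 under any similarity matrix
whose diagonal dominates its rows.  For similarity matrices, positive DAS
means the final state resembles the ancestral amino acid more than the
intermediates do; distance matrices reverse the sign convention.

Matrices can be read from AAindex flat files (H/D/M sections, lower
triangle) or plain 20x20 TSV tables.  Two matrices ship with the package
so the analysis runs without external data: an identity similarity matrix
and a synthetic physicochemical distance built from the Kyte-Doolittle
hydropathy scale and residue molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import EXCLUDED_STOP, STOP_SYMBOL, DoubleCombination
from .stats import ALPHA_GROUP, NEGATIVE, NEUTRAL, POSITIVE

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # AAindex row/column order

SIMILARITY = "similarity"
DISTANCE = "distance"


class MatrixFormatError(ValueError):
    """Unparseable or invalid amino-acid matrix input."""


@dataclass
class AAMatrix:
    """A symmetric 20x20 amino-acid similarity or distance matrix."""

    name: str
    kind: str  # similarity | distance
    labels: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (SIMILARITY, DISTANCE):
            raise MatrixFormatError(f"kind must be similarity|distance, got {self.kind!r}")
        if sorted(self.labels) != sorted(AA_ORDER):
            missing = set(AA_ORDER) - set(self.labels)
            raise MatrixFormatError(f"matrix must cover all 20 amino acids; missing {sorted(missing)}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise MatrixFormatError(f"expected a 20x20 table, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-6, equal_nan=False):
            raise MatrixFormatError("matrix is not symmetric")
        self.values = v
        self._index = {aa: i for i, aa in enumerate(self.labels)}

    def value(self, aa_from: str, aa_to: str) -> float:
        try:
            return float(self.values[self._index[aa_from], self._index[aa_to]])
        except KeyError as exc:
            raise KeyError(f"amino acid {exc} not in matrix {self.name}") from None

    def diagonal_row_maximal(self) -> bool:
        """True when every row's diagonal entry is its maximum (similarity)."""
        return bool(np.all(np.diag(self.values)[:, None] >= self.values))

    def flipped(self, name: Optional[str] = None) -> "AAMatrix":
        """The matrix with negated values and the opposite kind."""
        return AAMatrix(
            name=name or f"-{self.name}",
            kind=DISTANCE if self.kind == SIMILARITY else SIMILARITY,
            labels=self.labels,
            values=-self.values,
        )


def _parse_aaindex_rows(lines: List[str]) -> np.ndarray:
    values = np.full((20, 20), np.nan)
    for i, line in enumerate(lines):
        row = [math.nan if tok in ("-", "NA") else float(tok) for tok in line.split()]
        if len(row) not in (i + 1, 20):
            raise MatrixFormatError(
                f"matrix row {i + 1} has {len(row)} entries (expected {i + 1} or 20)"
            )
        values[i, : len(row)] = row
    # Mirror the lower triangle.
    iu = np.triu_indices(20, k=1)
    upper_missing = np.isnan(values[iu])
    values[iu[0][upper_missing], iu[1][upper_missing]] = values[
        iu[1][upper_missing], iu[0][upper_missing]
    ]
    if np.isnan(values).any():
        raise MatrixFormatError("matrix has missing entries after mirroring")
    return values


def load_aaindex(path, kind: str, name: Optional[str] = None) -> AAMatrix:
    """Read one matrix section from an AAindex2-style flat file.

    Parses the first entry: ``H`` (identifier), ``D`` (description) and the
    ``M rows = ..., cols = ...`` block of 20 lower-triangle rows.  AAindex
    does not encode whether an entry is a similarity or a distance, so
    ``kind`` must be supplied by the caller.
    """
    ident = None
    rows: List[str] = []
    in_matrix = False
    row_order = AA_ORDER
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                ident = line[2:].strip()
            elif line.startswith("M "):
                in_matrix = True
                header = line[2:]
                if "rows" in header:
                    row_order = header.split("rows")[1].split(",")[0].strip(" =")
            elif line.startswith("//"):
                break
            elif in_matrix:
                if line.strip():
                    rows.append(line)
    if len(rows) != 20:
        raise MatrixFormatError(f"{path}: expected 20 matrix rows, found {len(rows)}")
    values = _parse_aaindex_rows(rows)
    return AAMatrix(
        name=name or ident or str(path), kind=kind, labels=row_order, values=values
    )


def load_tsv(path, kind: str, name: Optional[str] = None) -> AAMatrix:
    """Read a plain 20x20 matrix TSV with amino-acid header row and column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = "".join(frame.index)
    if list(frame.columns) != list(frame.index):
        raise MatrixFormatError(f"{path}: row and column labels differ")
    return AAMatrix(
        name=name or str(path), kind=kind, labels=labels, values=frame.to_numpy(dtype=float)
    )


def load_matrix(path, format: str, kind: str, name: Optional[str] = None) -> AAMatrix:
    if format == "aaindex-flat":
        return load_aaindex(path, kind=kind, name=name)
    if format == "tsv":
        return load_tsv(path, kind=kind, name=name)
    raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Bundled matrices
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy and residue molecular weight (Da); both are
# textbook scales, combined into a synthetic two-property distance.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_MOLWEIGHT = {
    "A": 89.1, "R": 174.2, "N": 132.1, "D": 133.1, "C": 121.2, "Q": 146.2,
    "E": 147.1, "G": 75.1, "H": 155.2, "I": 131.2, "L": 131.2, "K": 146.2,
    "M": 149.2, "F": 165.2, "P": 115.1, "S": 105.1, "T": 119.1, "W": 204.2,
    "Y": 181.2, "V": 117.1,
}


def identity_matrix() -> AAMatrix:
    """Similarity matrix with 1 on the diagonal and 0 elsewhere."""
    return AAMatrix(
        name="identity", kind=SIMILARITY, labels=AA_ORDER, values=np.eye(20)
    )


def physchem_distance_matrix() -> AAMatrix:
    """Synthetic physicochemical distance: Euclidean over z-scored
    hydropathy and molecular weight (diagonal 0)."""
    h = np.array([_HYDROPATHY[a] for a in AA_ORDER])
    w = np.array([_MOLWEIGHT[a] for a in AA_ORDER])
    h = (h - h.mean()) / h.std()
    w = (w - w.mean()) / w.std()
    d = np.sqrt((h[:, None] - h[None, :]) ** 2 + (w[:, None] - w[None, :]) ** 2)
    return AAMatrix(name="physchem_distance", kind=DISTANCE, labels=AA_ORDER, values=d)


def bundled_matrices() -> List[AAMatrix]:
    return [identity_matrix(), physchem_distance_matrix()]


# ---------------------------------------------------------------------------
# DAS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DASRecord:
    combination: Tuple[str, str]
    label: str
    matrix: str
    s_of: float
    s_oi: float

    @property
    def das(self) -> float:
        return self.s_of - self.s_oi


def das(combination: DoubleCombination, matrix: AAMatrix) -> DASRecord:
    """DAS for one combination under one matrix.

    Synonymous steps contribute the diagonal (self-comparison) value, so
    the metric is defined for SN and NS combinations as well as NN.
    Combinations with stop intermediates are not scoreable.
    """
    if combination.label == EXCLUDED_STOP:
        raise ValueError("DAS undefined for stop-intermediate combinations")
    aa_anc, aa_i1, aa_i2, aa_fin = combination.amino_acids
    if STOP_SYMBOL in (aa_anc, aa_i1, aa_i2, aa_fin):
        raise ValueError("DAS undefined for stop amino acids")
    s_of = matrix.value(aa_anc, aa_fin)
    s_oi = 0.5 * (matrix.value(aa_anc, aa_i1) + matrix.value(aa_anc, aa_i2))
    return DASRecord(
        combination=(combination.ancestral, combination.final),
        label=combination.label,
        matrix=matrix.name,
        s_of=s_of,
        s_oi=s_oi,
    )


@dataclass(frozen=True)
class DASGroupComparison:
    group_a: str
    group_b: str
    p_u: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    expected_direction: bool  # difference sign agrees with matrix kind


def das_group_compare(
    das_by_regime: Dict[str, Sequence[float]],
    matrix: AAMatrix,
    alpha: float = ALPHA_GROUP,
) -> List[DASGroupComparison]:
    """Pairwise rank-sum comparisons of DAS values between regime groups.

    Compares positive vs negative, positive vs neutral and neutral vs
    negative where both groups are non-empty; pairs with an empty side are
    skipped.  ``expected_direction`` records whether the observed mean
    difference has the sign implied by the matrix kind (similarity:
    positively selected combinations should score higher; distance:
    lower).
    """
    order = [(POSITIVE, NEGATIVE), (POSITIVE, NEUTRAL), (NEUTRAL, NEGATIVE)]
    out = []
    for ga, gb in order:
        xs = list(das_by_regime.get(ga, []))
        ys = list(das_by_regime.get(gb, []))
        if not xs or not ys:
            continue
        p_u = float(sps.mannwhitneyu(xs, ys, alternative="two-sided").pvalue)
        mean_a, mean_b = float(np.mean(xs)), float(np.mean(ys))
        if matrix.kind == SIMILARITY:
            expected = mean_a >= mean_b
        else:
            expected = mean_a <= mean_b
        out.append(
            DASGroupComparison(
                group_a=ga,
                group_b=gb,
                p_u=p_u,
                mean_a=mean_a,
                mean_b=mean_b,
                n_a=len(xs),
                n_b=len(ys),
                expected_direction=expected,
            )
        )
    return out


def das_dataframe(
    combinations: Sequence[DoubleCombination], matrices: Sequence[AAMatrix]
) -> pd.DataFrame:
    """DAS per combination x matrix as a flat table."""
    rows = []
    for m in matrices:
        for c in combinations:
            if c.label == EXCLUDED_STOP:
                continue
            rec = das(c, m)
            rows.append(
                {
                    "ancestral": c.ancestral,
                    "final": c.final,
                    "label": c.label,
                    "matrix": m.name,
                    "kind": m.kind,
                    "s_of": rec.s_of,
                    "s_oi": rec.s_oi,
                    "das": rec.das,
                }
            )
    return pd.DataFrame(rows)
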