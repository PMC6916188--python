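"""Selection statistics on double substitutions.

The selection statistic is the double fraction DF = b / (a1 + a2 + b):
the share of observed instances of a double substitution among all
instances that start with one of its two single-substitution steps.  DF
estimates the substitution rate of the *second* step; comparing it to the
DF of the base-change-matched synonymous null model separates selection on
the second step from mutational biases (including multi-nucleotide
mutations, which inflate adjacent doubles in codons and nulls alike).

Inference layers:

* per-combination: Fisher's exact test on [[b_n, a1n+a2n], [b_s, a1s+a2s]]
  against the matched null, Benjamini-Hochberg corrected across the family
  of tested combinations; direction read from the DF comparison
  (higher = positive selection on the second step, lower = purifying);
* group level: two-sample t and Wilcoxon rank-sum tests between the DF
  values of a combination class and those of a null model (alpha 0.01);
* fast vs slow genes: paired t and Wilcoxon signed-rank tests on
  per-combination DF in the two gene speed classes (alpha 0.01);
* simultaneous double mutations: DM = f(b) - f(a1) f(a2) on null windows,
  with f(x) = x / ANC; DM feeds the adjusted DF b' = b - round(DM * ANC)
  used to re-test the NS class after removing the mutational contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genetic_code import NS, SS
from .null_models import NullCountsRecord
from .parsimony import CountsRecord, GeneCounts

ALPHA_GROUP = 0.01
ALPHA_BH = 0.05
MIN_TOTAL_DEFAULT = 5

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"

FAST = "fast"
SLOW = "slow"


@dataclass(frozen=True)
class DFRecord:
    """DF plus the per-lineage frequencies f(x) = x / ANC behind it."""

    a1: int
    a2: int
    b: int
    anc_count: int

    @property
    def total(self) -> int:
        return self.a1 + self.a2 + self.b

    @property
    def df(self) -> float:
        """b/(a1+a2+b); NaN when no instances were observed."""
        return self.b / self.total if self.total > 0 else math.nan

    @property
    def defined(self) -> bool:
        return self.total > 0

    def f(self, count: int) -> float:
        if self.anc_count <= 0:
            raise ValueError("ANC must be positive to compute frequencies")
        return count / self.anc_count

    @property
    def f_b(self) -> float:
        return self.f(self.b)

    @property
    def f_a1(self) -> float:
        return self.f(self.a1)

    @property
    def f_a2(self) -> float:
        return self.f(self.a2)


def df(counts) -> DFRecord:
    """Build a DFRecord from any record carrying a1, a2, b, anc_count."""
    rec = DFRecord(
        a1=int(counts.a1), a2=int(counts.a2), b=int(counts.b), anc_count=int(counts.anc_count)
    )
    if min(rec.a1, rec.a2, rec.b) < 0:
        raise ValueError("negative counts")
    return rec


def double_fraction(a1: int, a2: int, b: int) -> float:
    total = a1 + a2 + b
    if min(a1, a2, b) < 0:
        raise ValueError("negative counts")
    return b / total if total > 0 else math.nan


# ---------------------------------------------------------------------------
# Per-combination Fisher tests with BH correction
# ---------------------------------------------------------------------------


@dataclass
class RegimeCall:
    """Selection call for one combination against its matched null."""

    combination: Tuple[str, str]  # (ancestral, final)
    label: str
    p_value: float
    p_adjusted: float
    direction: str  # "above" | "below" | "equal"
    regime: str  # positive | negative | neutral
    df_codon: float
    df_null: float
    sufficient: bool


def fisher_test(counts_codon, counts_null) -> Tuple[float, str]:
    """Two-sided Fisher p and DF direction for one codon/null pair.

    Table orientation: [[b_n, a1n+a2n], [b_s, a1s+a2s]].  Degenerate
    tables (an all-zero margin) return p = 1.
    """
    bn, an = counts_codon.b, counts_codon.a1 + counts_codon.a2
    bs, as_ = counts_null.b, counts_null.a1 + counts_null.a2
    if (bn + an == 0) or (bs + as_ == 0) or (bn + bs == 0) or (an + as_ == 0):
        return 1.0, "equal"
    _, p = sps.fisher_exact([[bn, an], [bs, as_]], alternative="two-sided")
    dfn = bn / (bn + an)
    dfs = bs / (bs + as_)
    if dfn > dfs:
        direction = "above"
    elif dfn < dfs:
        direction = "below"
    else:
        direction = "equal"
    return float(p), direction


def call_regimes(
    pairs: Sequence[Tuple[Tuple[str, str], str, CountsRecord, NullCountsRecord]],
    alpha_bh: float = ALPHA_BH,
    min_total: int = MIN_TOTAL_DEFAULT,
) -> List[RegimeCall]:
    """Fisher tests for a family of (combination, null) pairs, BH-corrected.

    ``pairs`` holds ((ancestral, final), class label, codon counts, null
    counts).  The BH family is exactly the set of pairs passed in one call.
    A pair with fewer than ``min_total`` total instances on either side is
    reported but flagged insufficient and called neutral regardless of p.
    """
    if not pairs:
        return []
    raw = []
    directions = []
    for _, _, cc, nc in pairs:
        p, direction = fisher_test(cc, nc)
        raw.append(p)
        directions.append(direction)
    rejected, p_adj, _, _ = multipletests(raw, alpha=alpha_bh, method="fdr_bh")
    calls = []
    for (combo, label, cc, nc), p, padj, rej, direction in zip(
        pairs, raw, p_adj, rejected, directions
    ):
        sufficient = cc.total >= min_total and nc.total >= min_total
        if rej and sufficient and direction == "above":
            regime = POSITIVE
        elif rej and sufficient and direction == "below":
            regime = NEGATIVE
        else:
            regime = NEUTRAL
        calls.append(
            RegimeCall(
                combination=combo,
                label=label,
                p_value=float(p),
                p_adjusted=float(padj),
                direction=direction,
                regime=regime,
                df_codon=double_fraction(cc.a1, cc.a2, cc.b),
                df_null=double_fraction(nc.a1, nc.a2, nc.b),
                sufficient=sufficient,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Group-level and paired comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    p_t: float  # two-sample t test (NaN when unavailable)
    p_u: float  # Wilcoxon rank-sum / Mann-Whitney U
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int

    def significant(self, alpha: float = ALPHA_GROUP) -> bool:
        return self.p_t < alpha and self.p_u < alpha


def group_compare(df_x: Sequence[float], df_y: Sequence[float]) -> GroupTestResult:
    """Two-sample t and rank-sum tests between two sets of DF values.

    NaN DF values (undefined, zero-instance combinations) are dropped.
    With a single observation on a side the t test is reported as NaN.
    """
    x = np.asarray([v for v in df_x if not math.isnan(v)], dtype=float)
    y = np.asarray([v for v in df_y if not math.isnan(v)], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("group comparison requires non-empty samples")
    if x.size >= 2 and y.size >= 2:
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            p_t = 1.0  # identical constant samples
        else:
            p_t = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        p_t = math.nan
    p_u = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return GroupTestResult(
        p_t=p_t,
        p_u=p_u,
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=int(x.size),
        n_y=int(y.size),
    )


@dataclass(frozen=True)
class PairedTestResult:
    p_t: float  # paired t test
    p_w: float  # Wilcoxon signed-rank
    mean_diff: float  # mean(fast - slow)
    n: int

    def significant(self, alpha: float = ALPHA_GROUP) -> bool:
        return self.p_t < alpha and self.p_w < alpha


def fast_slow_compare(
    df_fast: Dict[Tuple[str, str], float], df_slow: Dict[Tuple[str, str], float]
) -> PairedTestResult:
    """Paired t and signed-rank tests of per-combination DF, fast vs slow.

    Pairs are formed by combination key; keys missing or NaN on either
    side are dropped.  Raises on fewer than two usable pairs.
    """
    keys = sorted(set(df_fast) & set(df_slow))
    pairs = [
        (df_fast[k], df_slow[k])
        for k in keys
        if not (math.isnan(df_fast[k]) or math.isnan(df_slow[k]))
    ]
    if len(pairs) < 2:
        raise ValueError(f"need >=2 shared combination keys, have {len(pairs)}")
    fast = np.array([p[0] for p in pairs])
    slow = np.array([p[1] for p in pairs])
    diff = fast - slow
    if np.all(diff == 0):
        p_t, p_w = 1.0, 1.0
    else:
        p_t = float(sps.ttest_rel(fast, slow).pvalue)
        p_w = float(sps.wilcoxon(fast, slow).pvalue)
    return PairedTestResult(
        p_t=p_t, p_w=p_w, mean_diff=float(diff.mean()), n=len(pairs)
    )


# ---------------------------------------------------------------------------
# Simultaneous double mutation estimation and the adjusted DF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DMEstimate:
    """Simultaneous double-mutation frequency from one null window key.

    DM = f(b) - f(a1) f(a2); a negative value (observed doubles below the
    product of singles) is attributed to noise, flagged, and excluded from
    aggregate means.
    """

    f_b: float
    product: float

    @property
    def dm(self) -> float:
        return self.f_b - self.product

    @property
    def negative(self) -> bool:
        return self.dm < 0


def dm_estimate(null_record) -> DMEstimate:
    if null_record.anc_count <= 0:
        raise ValueError("DM estimation requires ANC > 0")
    anc = null_record.anc_count
    f_b = null_record.b / anc
    product = (null_record.a1 / anc) * (null_record.a2 / anc)
    return DMEstimate(f_b=f_b, product=product)


def pooled_dm(null_records: Iterable) -> DMEstimate:
    """Configuration-level DM pooled over null keys.

    f(b) = sum(b) / sum(ANC) and the product term is the sum of per-key
    expected sequential doubles a1 a2 / ANC over the same denominator.
    Pooling lets per-key noise cancel instead of being rectified, which
    matters when individual keys hold only a handful of doubles.
    """
    sum_b = sum_anc = 0.0
    sum_seq = 0.0
    n = 0
    for rec in null_records:
        if rec.anc_count <= 0:
            continue
        sum_b += rec.b
        sum_anc += rec.anc_count
        sum_seq += rec.a1 * rec.a2 / rec.anc_count
        n += 1
    if n == 0 or sum_anc == 0:
        raise ValueError("pooled DM requires at least one key with ANC > 0")
    return DMEstimate(f_b=sum_b / sum_anc, product=sum_seq / sum_anc)


def mean_dm(estimates: Iterable[DMEstimate]) -> float:
    """Mean DM over keys, excluding the flagged negative estimates."""
    values = [e.dm for e in estimates if not e.negative]
    if not values:
        return math.nan
    return float(np.mean(values))


def adjusted_df(counts: CountsRecord, dm: DMEstimate, label: str) -> DFRecord:
    """DF after subtracting the estimated simultaneous-mutation doubles.

    b' = max(0, b - round(DM * ANC)).  Only meaningful for classes whose
    double substitution is synonymous end-to-end (NS and SS): for SN/NN a
    simultaneous double mutation is itself non-synonymous, hence subject
    to selection, and the synonymous DM estimate does not transfer.
    """
    if label not in (NS, SS):
        raise ValueError(f"adjusted DF is defined for NS/SS only, not {label}")
    removed = max(0.0, dm.dm) * counts.anc_count
    b_adj = max(0, counts.b - int(round(removed)))
    return DFRecord(a1=counts.a1, a2=counts.a2, b=b_adj, anc_count=counts.anc_count)


def expected_ns_neutral(counts_n: CountsRecord, counts_s) -> Tuple[float, float]:
    """Expected (b, DF) of a codon double under a neutral second step.

    Scales the null model's second-step rate b_s/(a1s+a2s) by the codon's
    observed single-substitution supply: b_n_exp = (a1n+a2n) b_s/(a1s+a2s).
    In the extreme case of a lethal intermediate (a2n = 0, a1n = a1s) with
    a symmetric null (a1s = a2s) this reduces to DF_n = (b_s/2)/(a1s + b_s/2).
    Returns (NaN, NaN) when the null has no single instances.
    """
    singles_s = counts_s.a1 + counts_s.a2
    if singles_s == 0:
        return math.nan, math.nan
    singles_n = counts_n.a1 + counts_n.a2
    b_exp = singles_n * counts_s.b / singles_s
    denom = singles_n + b_exp
    df_exp = b_exp / denom if denom > 0 else math.nan
    return float(b_exp), float(df_exp)


# ---------------------------------------------------------------------------
# Gene rates and the fast/slow split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRateRecord:
    gene_id: str
    dn: float
    ds: float
    ratio: float  # NaN when dS = 0
    speed: Optional[str]  # fast | slow | None (excluded)


def gene_rates(gene_counts: Sequence[GeneCounts]) -> List[GeneRateRecord]:
    """Per-gene dN, dS and dN/dS with a median split into fast/slow.

    dN and dS are single-substitution events per Nei-Gojobori-style site
    count on the resolved ancestral codons (no multiple-hit correction;
    the triplets are close).  Genes with dS = 0 have an undefined ratio
    and are excluded from the split; ties at the median go to slow.
    """
    prelim = []
    for g in gene_counts:
        dn = g.n_events / g.n_sites if g.n_sites > 0 else math.nan
        ds = g.s_events / g.s_sites if g.s_sites > 0 else math.nan
        if ds and ds > 0 and not math.isnan(dn):
            ratio = dn / ds
        else:
            ratio = math.nan
        prelim.append((g.gene_id, dn, ds, ratio))
    ratios = [r for _, _, _, r in prelim if not math.isnan(r)]
    median = float(np.median(ratios)) if ratios else math.nan
    out = []
    for gene_id, dn, ds, ratio in prelim:
        if math.isnan(ratio):
            speed = None
        elif ratio > median:
            speed = FAST
        else:
            speed = SLOW
        out.append(GeneRateRecord(gene_id=gene_id, dn=dn, ds=ds, ratio=ratio, speed=speed))
    return out


def split_gene_ids(records: Sequence[GeneRateRecord]) -> Tuple[set, set]:
    """(fast gene ids, slow gene ids); undefined-ratio genes in neither."""
    fast = {r.gene_id for r in records if r.speed == FAST}
    slow = {r.gene_id for r in records if r.speed == SLOW}
    return fast, slow
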