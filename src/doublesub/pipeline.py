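"""End-to-end analysis: tally -> null models -> selection calls -> report.

``analyze`` runs the whole inference on a set of triplet alignments:

1. tally single/double substitutions and ancestral opportunities per codon
   combination;
2. scan the same alignments for NM1/NM2 null windows;
3. Fisher-test every combination against its base-change-matched null,
   BH-correct across the family, and call selection regimes;
4. compare class-level DF distributions to each null model (t and
   rank-sum, alpha 0.01);
5. estimate simultaneous double-mutation frequencies from the null
   ledgers and re-test the NS class with the DM-adjusted DF;
6. split genes into fast/slow by median dN/dS and run the paired
   fast-vs-slow DF contrasts per class;
7. optionally stratify by transition/transversion composition and compare
   against intergenic pseudo-codon nulls.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple


import pandas as pd

from . import genetic_code as gc
from . import null_models as nm
from . import stats as st
from .genetic_code import NN, NS, SN, SS, DoubleCombination
from .parsimony import CODING, INTERGENIC, TallyResult, TripletAlignment, tally

MAIN_CLASSES = (SS, SN, NS, NN)
NM1 = "NM1"  # the two NM1 configurations pooled
NM2 = nm.NM2

TS_STRATA = ("ts_ts", "ts_tv", "tv_tv")


@dataclass
class AnalysisOptions:
    alpha: float = st.ALPHA_GROUP
    bh_alpha: float = st.ALPHA_BH
    min_total: int = st.MIN_TOTAL_DEFAULT
    fast_slow: bool = True
    ts_tv_strata: bool = False
    noncoding: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha, self.bh_alpha):
            if not (0 < a < 1):
                raise ValueError("alpha levels must lie in (0, 1)")


@dataclass
class CombinationResult:
    combo: DoubleCombination
    counts: "st.CountsRecord"
    matched: Optional[nm.MatchedKey]
    null_counts: Optional[nm.NullCountsRecord]

    @property
    def df(self) -> float:
        return st.double_fraction(self.counts.a1, self.counts.a2, self.counts.b)


@dataclass
class AnalysisResult:
    options: AnalysisOptions
    tally: TallyResult
    combinations: List[CombinationResult]
    null_records: Dict[nm.NullWindowKey, nm.NullCountsRecord]
    regime_calls: List[st.RegimeCall]
    group_tests: Dict[Tuple[str, str], st.GroupTestResult]
    dm_mean: Dict[str, float]
    adjusted_ns_test: Optional[st.PairedTestResult]
    gene_rates: List[st.GeneRateRecord]
    fast_slow_tests: Dict[str, st.PairedTestResult] = field(default_factory=dict)
    df_fast: Dict[str, Dict[Tuple[str, str], float]] = field(default_factory=dict)
    df_slow: Dict[str, Dict[Tuple[str, str], float]] = field(default_factory=dict)
    strata_group_tests: Dict[Tuple[str, str, str], st.GroupTestResult] = field(
        default_factory=dict
    )
    noncoding_tests: Dict[Tuple[str, str], st.GroupTestResult] = field(default_factory=dict)

    def regimes_by_combination(self) -> Dict[Tuple[str, str], str]:
        return {c.combination: c.regime for c in self.regime_calls}

    def class_df_values(self, label: str, min_total: Optional[int] = None) -> List[float]:
        """DF per combination of a class; combinations with fewer than
        ``min_total`` instances (default: the analysis threshold) give
        degenerate DF estimates and are excluded."""
        mt = self.options.min_total if min_total is None else min_total
        return [
            c.df
            for c in self.combinations
            if c.combo.label == label and c.counts.total >= max(mt, 1)
        ]

    def null_df_values(self, model: str, min_total: Optional[int] = None) -> List[float]:
        mt = self.options.min_total if min_total is None else min_total
        configs = (nm.NM1_23, nm.NM1_12) if model == NM1 else (nm.NM2,)
        values = []
        for key, rec in self.null_records.items():
            if key.config in configs and rec.total >= max(mt, 1):
                values.append(st.double_fraction(rec.a1, rec.a2, rec.b))
        return values


def combination_results(
    tallied: TallyResult,
    null_records: Dict[nm.NullWindowKey, nm.NullCountsRecord],
    catalogue: Optional[Sequence[DoubleCombination]] = None,
) -> List[CombinationResult]:
    """Counts + matched null for every analysable combination.

    EXCLUDED_STOP combinations are never tallied; SER combinations are
    kept out of the main analysis because no NM1 window with serine-like
    base changes exists (their matched key is unrealisable).
    """
    if catalogue is None:
        catalogue = gc.enumerate_combinations(include_excluded=False)
    out = []
    for combo in catalogue:
        if combo.label not in MAIN_CLASSES:
            continue
        counts = tallied.counts_record(combo)
        matched = nm.match_key(combo)
        null_counts = null_records.get(matched.key) if matched.realizable else None
        out.append(
            CombinationResult(
                combo=combo, counts=counts, matched=matched, null_counts=null_counts
            )
        )
    return out


def _testable_pairs(
    combos: Sequence[CombinationResult],
) -> List[Tuple[Tuple[str, str], str, "st.CountsRecord", nm.NullCountsRecord]]:
    """Pairs entering the Fisher/BH family: matched null exists, has
    opportunities, and at least one instance on each side."""
    pairs = []
    for c in combos:
        if c.null_counts is None or c.null_counts.anc_count == 0:
            continue
        if c.null_counts.total == 0 or c.counts.total == 0:
            continue
        pairs.append(
            ((c.combo.ancestral, c.combo.final), c.combo.label, c.counts, c.null_counts)
        )
    return pairs


def _ts_stratum(combo: DoubleCombination) -> str:
    n_ts = sum(combo.transitions)
    return TS_STRATA[2 - n_ts]


def _df_by_combination(
    tallied: TallyResult, combos: Sequence[DoubleCombination]
) -> Dict[str, Dict[Tuple[str, str], float]]:
    """Per-class maps (ancestral, final) -> DF for one tally."""
    out: Dict[str, Dict[Tuple[str, str], float]] = {label: {} for label in MAIN_CLASSES}
    for combo in combos:
        if combo.label not in MAIN_CLASSES:
            continue
        rec = tallied.counts_record(combo)
        out[combo.label][(combo.ancestral, combo.final)] = st.double_fraction(
            rec.a1, rec.a2, rec.b
        )
    return out


def analyze(
    alignments: Sequence[TripletAlignment],
    options: Optional[AnalysisOptions] = None,
) -> AnalysisResult:
    options = options or AnalysisOptions()
    coding = [a for a in alignments if a.kind == CODING]
    intergenic = [a for a in alignments if a.kind == INTERGENIC]
    catalogue = gc.enumerate_combinations(include_excluded=False)

    tallied = tally(coding)
    null_records = nm.scan_nulls(coding)
    combos = combination_results(tallied, null_records, catalogue)

    pairs = _testable_pairs(combos)
    regime_calls = st.call_regimes(
        pairs, alpha_bh=options.bh_alpha, min_total=options.min_total
    )

    result = AnalysisResult(
        options=options,
        tally=tallied,
        combinations=combos,
        null_records=null_records,
        regime_calls=regime_calls,
        group_tests={},
        dm_mean={},
        adjusted_ns_test=None,
        gene_rates=st.gene_rates(tallied.gene_counts),
    )

    # Class-level DF vs each null model.
    for label in MAIN_CLASSES:
        class_df = result.class_df_values(label)
        for model in (NM1, NM2):
            null_df = result.null_df_values(model)
            if len(class_df) >= 1 and len(null_df) >= 1:
                result.group_tests[(label, model)] = st.group_compare(class_df, null_df)

    # Simultaneous double-mutation estimates per null family.
    for model, configs in ((NM1, (nm.NM1_23, nm.NM1_12)), (NM2, (nm.NM2,))):
        estimates = [
            st.dm_estimate(rec)
            for key, rec in null_records.items()
            if key.config in configs and rec.anc_count > 0 and rec.total > 0
        ]
        result.dm_mean[model] = st.mean_dm(estimates) if estimates else math.nan

    # DM-adjusted DF for the NS class, paired against the matched null keys.
    # NS combinations are all non-adjacent, so the relevant simultaneous-
    # mutation rate is the NM2 one; it is pooled over keys because per-key
    # DM estimates are dominated by rectified noise at small double counts.
    adj_fast: Dict[Tuple[str, str], float] = {}
    adj_null: Dict[Tuple[str, str], float] = {}
    nm2_records = [
        rec for key, rec in null_records.items() if key.config == nm.NM2 and rec.anc_count > 0
    ]
    dm_nm2 = st.pooled_dm(nm2_records) if nm2_records else None
    for c in combos:
        if c.combo.label != NS or c.null_counts is None or dm_nm2 is None:
            continue
        if c.null_counts.anc_count == 0 or c.null_counts.total == 0 or c.counts.total == 0:
            continue
        adjusted = st.adjusted_df(c.counts, dm_nm2, c.combo.label)
        if adjusted.defined:
            key = (c.combo.ancestral, c.combo.final)
            adj_fast[key] = adjusted.df
            adj_null[key] = st.double_fraction(
                c.null_counts.a1, c.null_counts.a2, c.null_counts.b
            )
    if len(adj_fast) >= 2:
        result.adjusted_ns_test = st.fast_slow_compare(adj_fast, adj_null)

    # Fast vs slow genes: median dN/dS split, re-tally, paired contrasts.
    if options.fast_slow and coding:
        fast_ids, slow_ids = st.split_gene_ids(result.gene_rates)
        if fast_ids and slow_ids:
            tally_fast = tally([a for a in coding if a.gene_id in fast_ids])
            tally_slow = tally([a for a in coding if a.gene_id in slow_ids])
            result.df_fast = _df_by_combination(tally_fast, catalogue)
            result.df_slow = _df_by_combination(tally_slow, catalogue)
            for label in MAIN_CLASSES:
                try:
                    result.fast_slow_tests[label] = st.fast_slow_compare(
                        result.df_fast[label], result.df_slow[label]
                    )
                except ValueError:
                    pass  # too few shared combinations in this class

    # Transition/transversion strata: same group tests per stratum.
    if options.ts_tv_strata:
        for stratum in TS_STRATA:
            for label in MAIN_CLASSES:
                class_df = [
                    c.df
                    for c in combos
                    if c.combo.label == label
                    and _ts_stratum(c.combo) == stratum
                    and not math.isnan(c.df)
                ]
                for model in (NM1, NM2):
                    null_df = result.null_df_values(model)
                    if len(class_df) >= 2 and len(null_df) >= 2:
                        result.strata_group_tests[(stratum, label, model)] = st.group_compare(
                            class_df, null_df
                        )

    # Intergenic pseudo-codon nulls, adjacency-stratified.
    if options.noncoding and intergenic:
        frames = nm.scan_noncoding(intergenic)
        for adjacent, name in ((True, "noncoding_adjacent"), (False, "noncoding_nonadjacent")):
            null_df = nm.noncoding_df_values(frames, adjacent=adjacent)
            for label in MAIN_CLASSES:
                class_df = result.class_df_values(label)
                if len(class_df) >= 1 and len(null_df) >= 1:
                    result.noncoding_tests[(label, name)] = st.group_compare(
                        class_df, null_df
                    )

    return result


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def per_combination_dataframe(result: AnalysisResult) -> pd.DataFrame:
    calls = {c.combination: c for c in result.regime_calls}
    rows = []
    for c in result.combinations:
        key = (c.combo.ancestral, c.combo.final)
        call = calls.get(key)
        nc = c.null_counts
        rows.append(
            {
                "ancestral": c.combo.ancestral,
                "final": c.combo.final,
                "label": c.combo.label,
                "a1": c.counts.a1,
                "a2": c.counts.a2,
                "b": c.counts.b,
                "ANC": c.counts.anc_count,
                "df": c.df,
                "null_config": c.matched.key.config if c.matched else None,
                "null_realizable": bool(c.matched and c.matched.realizable),
                "null_a1": nc.a1 if nc else None,
                "null_a2": nc.a2 if nc else None,
                "null_b": nc.b if nc else None,
                "null_ANC": nc.anc_count if nc else None,
                "null_df": st.double_fraction(nc.a1, nc.a2, nc.b) if nc else None,
                "p": call.p_value if call else None,
                "p_bh": call.p_adjusted if call else None,
                "regime": call.regime if call else None,
                "sufficient": call.sufficient if call else False,
            }
        )
    return pd.DataFrame(rows)


def group_tests_dataframe(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for (label, model), test in sorted(result.group_tests.items()):
        rows.append(
            {
                "class": label,
                "null_model": model,
                "p_t": test.p_t,
                "p_u": test.p_u,
                "mean_class_df": test.mean_x,
                "mean_null_df": test.mean_y,
                "n_class": test.n_x,
                "n_null": test.n_y,
            }
        )
    return pd.DataFrame(rows)


def summary_dict(result: AnalysisResult) -> dict:
    regimes = [c.regime for c in result.regime_calls]
    summary = {
        "composition": result.tally.composition(),
        "n_tested_combinations": len(result.regime_calls),
        "n_positive": regimes.count(st.POSITIVE),
        "n_negative": regimes.count(st.NEGATIVE),
        "n_neutral": regimes.count(st.NEUTRAL),
        "dm_mean": {k: (None if math.isnan(v) else v) for k, v in result.dm_mean.items()},
        "group_tests": {
            f"{label}_vs_{model}": {"p_t": t.p_t, "p_u": t.p_u}
            for (label, model), t in sorted(result.group_tests.items())
        },
        "fast_slow": {
            label: {"p_t": t.p_t, "p_w": t.p_w, "mean_fast_minus_slow": t.mean_diff, "n": t.n}
            for label, t in sorted(result.fast_slow_tests.items())
        },
    }
    if result.adjusted_ns_test is not None:
        t = result.adjusted_ns_test
        summary["adjusted_ns_vs_null"] = {
            "p_t": t.p_t,
            "p_w": t.p_w,
            "mean_adjusted_minus_null": t.mean_diff,
        }
    if result.noncoding_tests:
        summary["noncoding_tests"] = {
            f"{label}_vs_{name}": {"p_t": t.p_t, "p_u": t.p_u}
            for (label, name), t in sorted(result.noncoding_tests.items())
        }
    return summary


def write_report(result: AnalysisResult, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    per_combination_dataframe(result).to_csv(
        os.path.join(outdir, "per_combination.tsv"), sep="\t", index=False
    )
    group_tests_dataframe(result).to_csv(
        os.path.join(outdir, "group_tests.tsv"), sep="\t", index=False
    )
    nm.ledger_dataframe(result.null_records).to_csv(
        os.path.join(outdir, "null_ledger.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "dN": r.dn,
                "dS": r.ds,
                "dN_dS": r.ratio,
                "speed": r.speed,
            }
            for r in result.gene_rates
        ]
    ).to_csv(os.path.join(outdir, "gene_rates.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary_dict(result), fh, indent=2, default=float)
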