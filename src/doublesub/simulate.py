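"""Forward simulator for genome triplets with codon-level selection.

Generates an ancestral genome (protein-coding genes plus optional
intergenic tracts) and evolves it independently along three branches --
one outgroup and two ingroups -- recording every accepted mutation in a
ground-truth log.  The mutational process is sequential proposal/
acceptance rather than a rate-matrix exponential so that simultaneous
adjacent double mutations and state-dependent selection are exact by
construction:

* each proposal is a single point mutation with probability 1 - delta, or
  a simultaneous change of two adjacent bases with probability delta;
* base changes follow a transition/transversion kernel with ratio kappa;
* acceptance: intergenic and synonymous changes always fix; changes
  creating a stop codon never fix; non-synonymous changes fix with the
  gene's fitness weight w_g; a change that restores the ancestral amino
  acid at a codon that currently differs from it always fixes.

With the reversion boost on, fixation of a deleterious non-synonymous
change can additionally trigger a *compensating* substitution on the same
branch: with probability min(1, c (1 - w_g) / w_g) -- odds proportional
to the fitness deficit the gene tolerates, c = ``reversion_prob`` -- a
single-base change restoring the ancestral amino acid, drawn from the
kappa-weighted kernel over the restoring options, fixes immediately.
This is the fitness-valley crossing regime: per-proposal acceptance is
capped at the synonymous baseline, so positive selection above that
baseline (an advantageous mutation fixing faster than a neutral one) has
to be expressed as directed compensation rather than as an acceptance
probability.  Because the trigger rate scales as w_g and the compensation
odds as (1 - w_g)/w_g, the resulting double-substitution supply is nearly
constant across gene speed classes while the single-substitution
denominator is not -- the configuration that separates DF between fast
and slow genes.

Gene fitness is two-point by default (a fast and a slow class), giving
the downstream dN/dS median split a known truth.  Ingroup branches are
kept much shorter than the outgroup branch so parsimony stays reliable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .genetic_code import AA_TABLE, BASES, SYN_TABLE, STOP_TABLE
from .null_models import NM1_12, NM1_23, NullWindowKey
from .parsimony import CODING, INTERGENIC, TripletAlignment

OUTGROUP = "outgroup"
INGROUP_1 = "ingroup_1"
INGROUP_2 = "ingroup_2"
BRANCHES = (OUTGROUP, INGROUP_1, INGROUP_2)

ACCEPT_NEUTRAL = "neutral"
ACCEPT_FITNESS = "fitness"
ACCEPT_REVERSION = "reversion"

# Transition partner and the two transversion partners per base index.
_TRANSITION_OF = np.array([2, 3, 0, 1], dtype=np.int8)
_TRANSVERSIONS_OF = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


@dataclass
class SimulationConfig:
    """Generative parameters; the defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 400
    codons_per_gene: int = 500
    codon_weights: Optional[Sequence[float]] = None  # over the 61 sense codons
    outgroup_rate: float = 0.15  # expected proposals per site
    ingroup_rates: Tuple[float, float] = (0.04, 0.04)
    kappa: float = 2.0  # transition/transversion ratio
    delta: float = 0.05  # simultaneous adjacent double-mutation fraction
    w_fast: float = 0.5  # fitness weight of fast-evolving genes
    w_slow: float = 0.1
    fast_fraction: float = 0.5
    reversion_boost: bool = True
    reversion_prob: float = 0.05  # base odds factor for compensation
    intergenic_fraction: float = 0.1  # intergenic bases per coding base

    def __post_init__(self) -> None:
        if not (0 <= self.delta < 1):
            raise ValueError("delta must lie in [0, 1)")
        for r in (self.outgroup_rate, *self.ingroup_rates):
            if r < 0:
                raise ValueError("branch rates must be >= 0")
        for w in (self.w_fast, self.w_slow):
            if not (0 < w <= 1):
                raise ValueError("fitness weights must lie in (0, 1]")
        if self.reversion_prob < 0:
            raise ValueError("reversion_prob must be >= 0")
        if self.codon_weights is not None:
            w = np.asarray(self.codon_weights, dtype=float)
            if w.size != len(gc.SENSE_CODONS) or w.min() < 0 or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    "codon_weights must be a distribution over the 61 sense codons"
                )

    @classmethod
    def neutral(cls, **kwargs) -> "SimulationConfig":
        """No selection: w = 1 everywhere, reversion boost off."""
        kwargs.setdefault("w_fast", 1.0)
        kwargs.setdefault("w_slow", 1.0)
        kwargs.setdefault("reversion_boost", False)
        return cls(**kwargs)


@dataclass(frozen=True)
class TruthEvent:
    """One accepted mutation on one branch."""

    region_id: str
    kind: str  # coding | intergenic
    branch: str
    position: int  # 0-based within the region, 5'-most changed base
    before: str
    after: str
    simultaneous: bool
    acceptance: str  # neutral | fitness | reversion


@dataclass
class TruthLog:
    events: List[TruthEvent] = field(default_factory=list)

    def for_branch(self, branch: str) -> List[TruthEvent]:
        return [e for e in self.events if e.branch == branch]

    def simultaneous_fraction(self) -> float:
        if not self.events:
            return float("nan")
        return sum(e.simultaneous for e in self.events) / len(self.events)

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])


@dataclass
class Region:
    region_id: str
    kind: str
    ancestor: np.ndarray  # int8 base indices
    w: float = 1.0
    speed: Optional[str] = None


@dataclass
class SimulationResult:
    config: SimulationConfig
    regions: List[Region]
    tips: Dict[str, Dict[str, np.ndarray]]  # branch -> region_id -> bases
    truth: TruthLog

    @property
    def coding_regions(self) -> List[Region]:
        return [r for r in self.regions if r.kind == CODING]

    @property
    def gene_speed_truth(self) -> Dict[str, str]:
        return {r.region_id: r.speed for r in self.coding_regions if r.speed}

    def alignments(self, kind: Optional[str] = None) -> List[TripletAlignment]:
        out = []
        for region in self.regions:
            if kind is not None and region.kind != kind:
                continue
            seqs = tuple(
                _decode(self.tips[b][region.region_id]) for b in BRANCHES
            )
            out.append(
                TripletAlignment(
                    gene_id=region.region_id,
                    ids=BRANCHES,
                    seqs=seqs,  # type: ignore[arg-type]
                    outgroup_id=OUTGROUP,
                    kind=region.kind,
                )
            )
        return out

    def write(self, outdir) -> None:
        """FASTA per region, manifest TSV, truth-log TSV, config JSON."""
        os.makedirs(outdir, exist_ok=True)
        rows = []
        for aln in self.alignments():
            fasta = os.path.join(outdir, f"{aln.gene_id}.fasta")
            with open(fasta, "w") as fh:
                for sid, seq in zip(aln.ids, aln.seqs):
                    fh.write(f">{sid}\n{seq}\n")
            rows.append(
                {
                    "gene_id": aln.gene_id,
                    "path": f"{aln.gene_id}.fasta",
                    "outgroup_id": aln.outgroup_id,
                    "kind": aln.kind,
                }
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "manifest.tsv"), sep="\t", index=False
        )
        self.truth.dataframe().to_csv(
            os.path.join(outdir, "truth_log.tsv"), sep="\t", index=False
        )
        cfg = asdict(self.config)
        cfg["codon_weights"] = (
            list(self.config.codon_weights) if self.config.codon_weights is not None else None
        )
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=2)


def _decode(bases: np.ndarray) -> str:
    return "".join(BASES[b] for b in bases)


def _encode(seq: str) -> np.ndarray:
    return np.array([gc.BASE_INDEX[b] for b in seq], dtype=np.int8)


# ---------------------------------------------------------------------------
# Ancestor generation
# ---------------------------------------------------------------------------


def generate_ancestor(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> List[Region]:
    """Draw the ancestral genome: stop-free genes plus intergenic tracts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = (
        np.asarray(config.codon_weights, dtype=float)
        if config.codon_weights is not None
        else np.full(len(gc.SENSE_CODONS), 1.0 / len(gc.SENSE_CODONS))
    )
    sense_idx = np.array([gc.codon_to_index(c) for c in gc.SENSE_CODONS])
    regions: List[Region] = []
    for g in range(config.n_genes):
        codons = rng.choice(sense_idx, size=config.codons_per_gene, p=weights)
        bases = gc.BASE_TABLE[codons].reshape(-1).astype(np.int8)
        fast = rng.random() < config.fast_fraction
        regions.append(
            Region(
                region_id=f"gene{g:05d}",
                kind=CODING,
                ancestor=bases,
                w=config.w_fast if fast else config.w_slow,
                speed="fast" if fast else "slow",
            )
        )
    # With zero genes the config still describes an intergenic-only genome
    # of one gene-equivalent of bases.
    gene_equivalents = max(config.n_genes, 1)
    total_intergenic = int(
        round(config.intergenic_fraction * gene_equivalents * config.codons_per_gene * 3)
    )
    tract = 999
    i = 0
    while total_intergenic > 0:
        length = min(tract, total_intergenic)
        bases = rng.integers(0, 4, size=length).astype(np.int8)
        regions.append(Region(region_id=f"ig{i:05d}", kind=INTERGENIC, ancestor=bases))
        total_intergenic -= length
        i += 1
    return regions


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------


def _codon_at(seq: np.ndarray, ci: int) -> int:
    return int(seq[3 * ci]) * 16 + int(seq[3 * ci + 1]) * 4 + int(seq[3 * ci + 2])


def evolve_branch(
    region: Region,
    branch: str,
    rate: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    log: TruthLog,
) -> np.ndarray:
    """Evolve one region along one branch; returns the derived sequence.

    All randomness is drawn up front from ``rng`` so runs are reproducible
    proposal-for-proposal under a fixed seed.
    """
    seq = region.ancestor.copy()
    L = seq.size
    if L == 0 or rate == 0:
        return seq
    coding = region.kind == CODING
    if coding:
        anc_codons = np.array([_codon_at(region.ancestor, k) for k in range(L // 3)])
        anc_aa = AA_TABLE[anc_codons]
    n_prop = int(rng.poisson(rate * L))
    if n_prop == 0:
        return seq
    u_double = rng.random(n_prop)
    u_pos = rng.random(n_prop)
    u_kernel = rng.random((n_prop, 2))
    u_pick = rng.integers(0, 2, size=(n_prop, 2))
    u_accept = rng.random(n_prop)
    u_comp = rng.random(n_prop)
    u_comp_pick = rng.random(n_prop)
    p_transition = config.kappa / (config.kappa + 2.0)
    if coding and config.reversion_boost and region.w < 1.0:
        p_comp = min(1.0, config.reversion_prob * (1.0 - region.w) / region.w)
    else:
        p_comp = 0.0

    for t in range(n_prop):
        simultaneous = L >= 2 and u_double[t] < config.delta
        if simultaneous:
            p0 = int(u_pos[t] * (L - 1))
            positions = (p0, p0 + 1)
        else:
            p0 = int(u_pos[t] * L)
            positions = (p0,)
        news = []
        for j, p in enumerate(positions):
            old = seq[p]
            if u_kernel[t, j] < p_transition:
                news.append(int(_TRANSITION_OF[old]))
            else:
                news.append(int(_TRANSVERSIONS_OF[old, u_pick[t, j]]))
        acceptance = ACCEPT_NEUTRAL
        if coding:
            prob = 1.0
            stop_hit = False
            for ci in sorted({p // 3 for p in positions}):
                cur = _codon_at(seq, ci)
                new_bases = seq[3 * ci : 3 * ci + 3].copy()
                for p, nb in zip(positions, news):
                    if p // 3 == ci:
                        new_bases[p % 3] = nb
                new = int(new_bases[0]) * 16 + int(new_bases[1]) * 4 + int(new_bases[2])
                if STOP_TABLE[new]:
                    stop_hit = True
                    break
                if AA_TABLE[new] == AA_TABLE[cur]:
                    continue
                if (
                    config.reversion_boost
                    and AA_TABLE[new] == anc_aa[ci]
                    and AA_TABLE[cur] != anc_aa[ci]
                ):
                    if acceptance == ACCEPT_NEUTRAL:
                        acceptance = ACCEPT_REVERSION
                    continue
                prob *= region.w
                acceptance = ACCEPT_FITNESS
            if stop_hit:
                continue
            if prob < 1.0 and u_accept[t] >= prob:
                continue
        before = "".join(BASES[seq[p]] for p in positions)
        after = "".join(BASES[n] for n in news)
        for p, nb in zip(positions, news):
            seq[p] = nb
        log.events.append(
            TruthEvent(
                region_id=region.region_id,
                kind=region.kind,
                branch=branch,
                position=positions[0],
                before=before,
                after=after,
                simultaneous=simultaneous,
                acceptance=acceptance,
            )
        )
        # Fitness-valley compensation: a fixed deleterious change may be
        # followed by a positively selected restoring substitution.
        if (
            acceptance == ACCEPT_FITNESS
            and not simultaneous
            and p_comp > 0.0
            and u_comp[t] < p_comp
        ):
            ci = positions[0] // 3
            cur = _codon_at(seq, ci)
            if AA_TABLE[cur] != anc_aa[ci]:
                choice = _pick_restoring_change(
                    seq, ci, anc_aa[ci], p_transition, u_comp_pick[t]
                )
                if choice is not None:
                    p, nb = choice
                    log.events.append(
                        TruthEvent(
                            region_id=region.region_id,
                            kind=region.kind,
                            branch=branch,
                            position=p,
                            before=BASES[seq[p]],
                            after=BASES[nb],
                            simultaneous=False,
                            acceptance=ACCEPT_REVERSION,
                        )
                    )
                    seq[p] = nb
    return seq


def _pick_restoring_change(
    seq: np.ndarray, ci: int, target_aa: str, p_transition: float, u: float
) -> Optional[Tuple[int, int]]:
    """Kernel-weighted choice among single-base changes of codon ``ci``
    that restore ``target_aa``; None when no such change exists."""
    candidates: List[Tuple[int, int, float]] = []
    for off in range(3):
        p = 3 * ci + off
        old = int(seq[p])
        shift = 16 if off == 0 else (4 if off == 1 else 1)
        cur = _codon_at(seq, ci)
        for nb in range(4):
            if nb == old:
                continue
            variant = cur + (nb - old) * shift
            if AA_TABLE[variant] == target_aa:
                is_ts = nb == _TRANSITION_OF[old]
                weight = p_transition / 2.0 if is_ts else (1.0 - p_transition) / 4.0
                candidates.append((p, nb, weight))
    if not candidates:
        return None
    total = sum(w for _, _, w in candidates)
    acc = 0.0
    for p, nb, w in candidates:
        acc += w / total
        if u < acc:
            return p, nb
    return candidates[-1][:2]


def replay(ancestor: np.ndarray, events: Iterable[TruthEvent]) -> np.ndarray:
    """Apply logged events in order; must reproduce the tip exactly."""
    seq = ancestor.copy()
    for e in events:
        for k, (bb, ab) in enumerate(zip(e.before, e.after)):
            p = e.position + k
            if BASES[seq[p]] != bb:
                raise ValueError(
                    f"replay mismatch at {e.region_id}:{p} "
                    f"(have {BASES[seq[p]]}, log says {bb})"
                )
            seq[p] = gc.BASE_INDEX[ab]
    return seq


# ---------------------------------------------------------------------------
# Whole-triplet simulation
# ---------------------------------------------------------------------------


def simulate_triplet(config: SimulationConfig) -> SimulationResult:
    """Ancestor + three independent branches, with truth log."""
    rng = np.random.default_rng(config.seed)
    regions = generate_ancestor(config, rng)
    rates = {
        OUTGROUP: config.outgroup_rate,
        INGROUP_1: config.ingroup_rates[0],
        INGROUP_2: config.ingroup_rates[1],
    }
    truth = TruthLog()
    tips: Dict[str, Dict[str, np.ndarray]] = {b: {} for b in BRANCHES}
    for branch in BRANCHES:
        for region in regions:
            tips[branch][region.region_id] = evolve_branch(
                region, branch, rates[branch], config, rng, truth
            )
    return SimulationResult(config=config, regions=regions, tips=tips, truth=truth)


# ---------------------------------------------------------------------------
# Truth-based census of simultaneous doubles in null windows
# ---------------------------------------------------------------------------


def eligible_nm1_opportunities(result: SimulationResult) -> int:
    """Per-branch count of NM1-eligible ancestral windows (2 per window).

    The denominator for the truth-realised simultaneous-double frequency:
    adjacent codon pairs of the ancestral genes where codon *i* is
    fourfold-degenerate at its third position and codon *ii* is a
    leucine/arginine codon with a degenerate first position and a purine
    third position.
    """
    from .null_models import FOURFOLD3_TABLE, PURINE3_TABLE, TWOFOLD1_TABLE

    total = 0
    for region in result.coding_regions:
        codons = np.array(
            [_codon_at(region.ancestor, k) for k in range(region.ancestor.size // 3)]
        )
        if codons.size < 2:
            continue
        ci, cii = codons[:-1], codons[1:]
        total += int(
            (FOURFOLD3_TABLE[ci] & TWOFOLD1_TABLE[cii] & PURINE3_TABLE[cii]).sum()
        )
    return 2 * total


def truth_null_double_census(
    result: SimulationResult, visible_only: bool = False
) -> Dict[NullWindowKey, int]:
    """Count simultaneous double mutations realised at NM1 window sites.

    For each accepted simultaneous event on an ingroup branch that spans
    the third position of codon *i* and the first position of codon *ii*,
    starts from the pristine ancestral bases, lands in an NM1-eligible
    window and is synonymous in both host codons, increment the matching
    NM1_23 and NM1_12 keys.  This is the ground truth the DM estimator is
    meant to recover.

    With ``visible_only`` the census keeps only events that a parsimony
    scan of the tip alignments can observe: the outgroup and the other
    ingroup must still equal the ancestor over both window codons (the
    window stays resolvable) and the event branch's tip must differ from
    the ancestor at exactly the two event sites (no later hits in the
    window).  The unrestricted census is the raw mutational input; the
    visible census is the share of it that survives to be countable.
    """
    from .null_models import (
        FOURFOLD3_TABLE,
        PURINE3_TABLE,
        TWOFOLD1_TABLE,
    )

    regions = {r.region_id: r for r in result.regions}
    census: Dict[NullWindowKey, int] = {}

    def _event_visible(res: SimulationResult, ev: TruthEvent, codon_i: int) -> bool:
        anc = regions[ev.region_id].ancestor
        lo, hi = 3 * codon_i, 3 * codon_i + 6
        other = INGROUP_1 if ev.branch == INGROUP_2 else INGROUP_2
        out_tip = res.tips[OUTGROUP][ev.region_id][lo:hi]
        other_tip = res.tips[other][ev.region_id][lo:hi]
        own_tip = res.tips[ev.branch][ev.region_id][lo:hi]
        window_anc = anc[lo:hi]
        if not (np.array_equal(out_tip, window_anc) and np.array_equal(other_tip, window_anc)):
            return False
        expected = window_anc.copy()
        expected[2] = gc.BASE_INDEX[ev.after[0]]
        expected[3] = gc.BASE_INDEX[ev.after[1]]
        return bool(np.array_equal(own_tip, expected))
    for e in result.truth.events:
        if not e.simultaneous or e.kind != CODING:
            continue
        if e.branch == OUTGROUP:
            continue
        if e.position % 3 != 2:  # must span (codon i pos 3, codon ii pos 1)
            continue
        anc = regions[e.region_id].ancestor
        ci = e.position // 3
        anc_i = _codon_at(anc, ci)
        anc_ii = _codon_at(anc, ci + 1)
        if not (FOURFOLD3_TABLE[anc_i] and TWOFOLD1_TABLE[anc_ii] and PURINE3_TABLE[anc_ii]):
            continue
        # must start from the ancestral bases (no earlier hit at these sites)
        if e.before[0] != BASES[gc.BASE_TABLE[anc_i, 2]]:
            continue
        if e.before[1] != BASES[gc.BASE_TABLE[anc_ii, 0]]:
            continue
        new_i = anc_i - gc.BASE_TABLE[anc_i, 2] + gc.BASE_INDEX[e.after[0]]
        new_ii = anc_ii - gc.BASE_TABLE[anc_ii, 0] * 16 + gc.BASE_INDEX[e.after[1]] * 16
        if not (SYN_TABLE[anc_i, new_i] and SYN_TABLE[anc_ii, new_ii]):
            continue
        if visible_only and not _event_visible(result, e, ci):
            continue
        change1 = (e.before[0], e.after[0])
        change2 = (e.before[1], e.after[1])
        for cfg, const_base in (
            (NM1_23, BASES[gc.BASE_TABLE[anc_i, 1]]),
            (NM1_12, BASES[gc.BASE_TABLE[anc_ii, 1]]),
        ):
            key = NullWindowKey(
                config=cfg, change1=change1, change2=change2, constant=const_base
            )
            census[key] = census.get(key, 0) + 1
    return census
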