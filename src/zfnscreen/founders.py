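"""Pooled fluorescent-PCR founder screening and transmission estimation.

Each putative founder (mosaic, injected F0) is outcrossed to wild type and
its progeny genotyped in pools: with pools of ``s`` embryos and ``m`` wells,
``s*m`` embryos are screened and a mutation transmitted by a single embryo
is detectable, i.e. the design sensitivity is ``100/(s*m)`` percent.  The
standard layout pools 4 embryos/well into 15 wells (two columns of an
8x12 plate), screening 60 embryos per founder at 1.6% sensitivity and
6 founders per 96-well plate.

Fragment analysis reports, per well, peak sizes (bp) and heights.  Because
every F1 is at most heterozygous (outcross to wild type), one heterozygote
in a pool of 4 contributes 1 of 8 alleles, so its mutant peak carries ~1/8
of the total signal; carrier counts are estimated from the signal fraction.
Germline transmission frequency per allele is then estimated two ways from
the ``k`` of ``m`` positive pools: a conservative lower bound assuming one
heterozygote per positive pool (``100*k/(s*m)``), and a pooled-binomial
maximum-likelihood estimate ``100*(1-(1-k/m)^(1/s))`` that corrects for
pools containing more than one carrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class PoolPlan:
    """Design of a pooled founder screen."""

    pool_size: int            # s, embryos per well
    n_pools: int              # m, wells per founder
    n_embryos: int            # s * m
    sensitivity: float        # percent, minimal detectable transmission
    wells_per_founder: int
    founders_per_plate: int


@dataclass(frozen=True)
class Peak:
    size: float    # bp, from the internal size standard
    height: float  # arbitrary fluorescence units

    def __post_init__(self) -> None:
        if self.size <= 0 or self.height <= 0:
            raise ValueError("peak size and height must be positive")


@dataclass(frozen=True)
class PeakTable:
    """Fragment sizes and heights for one well."""

    well_id: str
    peaks: tuple[Peak, ...]


@dataclass(frozen=True)
class MutantPeak:
    size: float
    height: float
    net_delta: int      # bp relative to the wild-type fragment
    est_carriers: int   # estimated heterozygous embryos in the pool


@dataclass(frozen=True)
class PoolCall:
    well_id: str
    wt_peak: Peak | None
    mutant_peaks: tuple[MutantPeak, ...]
    failed: bool = False  # no wild-type-sized peak (amplification failure)


@dataclass(frozen=True)
class F1Call:
    well_id: str
    genotype: str          # 'wt' | 'het' | 'review'
    net_delta: int | None
    mutant_fraction: float
    flagged: bool


@dataclass(frozen=True)
class TransmissionEstimate:
    """Germline transmission frequency of one allele (percent)."""

    allele_id: str
    net_delta: int
    k_positive_pools: int
    lower_bound: float
    mle: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class ToxicityResult:
    n_dead: int
    n_deformed: int
    n_normal: int
    fraction_affected: float
    toxic: bool


def design_screen(
    n_embryos: int,
    pool_size: int,
    plate_wells: int = 96,
    wells_per_founder_columns: int = 2,
) -> PoolPlan:
    """Lay out a pooled screen on an 8-row PCR plate.

    Sensitivity (the lowest transmission frequency detectable, one carrier
    among ``n_embryos``) is printed truncated to one decimal, so 100/60
    reports as 1.6%.  Each founder occupies whole plate columns.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if n_embryos < 1 or n_embryos % pool_size != 0:
        raise ValueError(
            f"n_embryos={n_embryos} is not divisible by pool_size={pool_size}")
    if plate_wells % 8 != 0:
        raise ValueError("plate must have 8 rows (wells divisible by 8)")
    n_pools = n_embryos // pool_size
    wells_per_founder = wells_per_founder_columns * 8
    if n_pools > wells_per_founder:
        raise ValueError(
            f"{n_pools} pools do not fit in {wells_per_founder} wells "
            f"({wells_per_founder_columns} columns)")
    plate_columns = plate_wells // 8
    sensitivity = math.floor(1000.0 / n_embryos) / 10.0
    return PoolPlan(
        pool_size=pool_size,
        n_pools=n_pools,
        n_embryos=n_embryos,
        sensitivity=sensitivity,
        wells_per_founder=wells_per_founder,
        founders_per_plate=plate_columns // wells_per_founder_columns,
    )


def expected_mutant_fraction(n_het_embryos: int, pool_size: int) -> float:
    """Expected mutant signal fraction in a pool.

    Heterozygotes contribute one mutant allele each out of ``2*pool_size``
    total alleles, so one heterozygote in a pool of 4 gives 1/8 of the
    total signal.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not 0 <= n_het_embryos <= pool_size:
        raise ValueError(
            f"n_het_embryos={n_het_embryos} outside [0, {pool_size}]")
    return n_het_embryos / (2.0 * pool_size)


def merge_plus_a_peaks(peaks: tuple[Peak, ...] | list[Peak],
                       size_tol: float = 0.5) -> tuple[Peak, ...]:
    """Fold non-templated +A shadow peaks into their parent peak.

    Without PIG-tailed reverse primers, Taq adenylation splits each allele
    into peaks at x and x+1.  Peak pairs at (x, x+1) with the +1 peak
    smaller are merged into x, summing heights (total signal preserved).
    Idempotent.  Note a genuine +1 insertion allele is indistinguishable
    from the wild-type +A shadow — the reason PIG-tailing is preferred over
    computational merging.
    """
    ordered = sorted(peaks, key=lambda p: p.size)
    merged: list[Peak] = []
    consumed = [False] * len(ordered)
    for i, p in enumerate(ordered):
        if consumed[i]:
            continue
        height = p.height
        for j in range(i + 1, len(ordered)):
            if consumed[j]:
                continue
            q = ordered[j]
            if q.size > p.size + 1 + size_tol:
                break
            if abs(q.size - (p.size + 1)) <= size_tol and q.height < height:
                height += q.height
                consumed[j] = True
        merged.append(Peak(size=p.size, height=height))
    return tuple(merged)


def call_pool_peaks(
    table: PeakTable,
    wt_size: float,
    pool_size: int,
    min_rel_height: float = 0.05,
    size_tol: float = 0.5,
    merge_plus_a: bool = False,
) -> PoolCall:
    """Call mutant peaks and estimated carrier counts for one pooled well.

    The wild-type allele is always present in an outcross, so a well with
    no peak within ``size_tol`` of ``wt_size`` is flagged failed rather
    than called.  Mutant peaks are peaks away from the wild-type size whose
    height reaches ``min_rel_height`` of the total well signal (noise
    floor); carriers per mutant peak are estimated as
    ``round(height/total * 2*pool_size)``, clamped to [1, pool_size].
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    peaks = tuple(table.peaks)
    if merge_plus_a:
        peaks = merge_plus_a_peaks(peaks, size_tol=size_tol)
    wt_candidates = [p for p in peaks if abs(p.size - wt_size) <= size_tol]
    if not wt_candidates:
        return PoolCall(table.well_id, None, (), failed=True)
    wt_peak = min(wt_candidates, key=lambda p: abs(p.size - wt_size))
    total = sum(p.height for p in peaks)
    mutants = []
    for p in sorted(peaks, key=lambda q: q.size):
        if abs(p.size - wt_size) <= size_tol:
            continue
        if p.height < min_rel_height * total:
            continue
        est = round(p.height / total * 2 * pool_size)
        mutants.append(MutantPeak(
            size=p.size, height=p.height,
            net_delta=round(p.size - wt_size),
            est_carriers=min(max(est, 1), pool_size)))
    return PoolCall(table.well_id, wt_peak, tuple(mutants))


def genotype_f1(
    table: PeakTable,
    wt_size: float,
    min_rel_height: float = 0.05,
    size_tol: float = 0.5,
    het_band: tuple[float, float] = (0.3, 0.7),
) -> F1Call:
    """Genotype a single fish (fin clip) from its peak table.

    F1 from an outcross are at most heterozygous, so a heterozygote shows
    the wild-type peak plus exactly one mutant peak at ~half the signal.
    Wells with more than one mutant peak, or a mutant fraction outside
    ``het_band``, are flagged for manual review.
    """
    call = call_pool_peaks(table, wt_size, pool_size=1,
                           min_rel_height=min_rel_height, size_tol=size_tol)
    if call.failed:
        return F1Call(table.well_id, "review", None, 0.0, flagged=True)
    total = sum(p.height for p in table.peaks)
    if not call.mutant_peaks:
        return F1Call(table.well_id, "wt", None, 0.0, flagged=False)
    if len(call.mutant_peaks) > 1:
        return F1Call(table.well_id, "review", None,
                      sum(m.height for m in call.mutant_peaks) / total,
                      flagged=True)
    peak = call.mutant_peaks[0]
    frac = peak.height / total
    if het_band[0] <= frac <= het_band[1]:
        return F1Call(table.well_id, "het", peak.net_delta, frac, flagged=False)
    return F1Call(table.well_id, "review", peak.net_delta, frac, flagged=True)


def estimate_transmission(
    calls: list[PoolCall],
    plan: PoolPlan,
    ci_level: float = 0.95,
) -> dict[int, TransmissionEstimate]:
    """Per-allele germline transmission estimates for one founder.

    Alleles are keyed by ``net_delta`` (fragment analysis cannot separate
    same-size alleles of different sequence).  Failed wells are excluded
    from both the positive-pool count ``k`` and the denominator ``m``.

    The lower bound assumes exactly one heterozygote per positive pool.
    The MLE inverts the pool-positive probability: a pool of ``s`` embryos
    is negative iff all embryos are non-carriers, so with per-embryo
    transmission ``p`` the pool-positive probability is ``q = 1-(1-p)^s``;
    plugging the MLE ``q_hat = k/m`` gives ``p_hat = 1-(1-k/m)^(1/s)``.
    The CI inverts an exact (Clopper-Pearson) binomial interval on ``k``
    of ``m`` through the same transform.
    """
    usable = [c for c in calls if not c.failed]
    m = len(usable)
    if m == 0:
        raise ValueError("no usable (non-failed) wells")
    if m > plan.n_pools:
        raise ValueError(f"{m} wells exceed plan.n_pools={plan.n_pools}")
    s = plan.pool_size
    k_by_allele: dict[int, int] = {}
    for call in usable:
        for delta in {mp.net_delta for mp in call.mutant_peaks}:
            k_by_allele[delta] = k_by_allele.get(delta, 0) + 1

    def transform(q: float) -> float:
        return 100.0 * (1.0 - (1.0 - q) ** (1.0 / s))

    out: dict[int, TransmissionEstimate] = {}
    for delta, k in sorted(k_by_allele.items()):
        q_lo, q_hi = proportion_confint(k, m, alpha=1 - ci_level, method="beta")
        out[delta] = TransmissionEstimate(
            allele_id=f"{delta:+d}bp",
            net_delta=delta,
            k_positive_pools=k,
            lower_bound=100.0 * k / (s * m),
            mle=transform(k / m),
            ci=(transform(q_lo), transform(q_hi)),
        )
    return out


def predicted_fragment_size(wt_size: float, net_delta: float) -> float:
    """Fragment size of an allele with a net length change of ``net_delta``."""
    size = wt_size + net_delta
    if size <= 0:
        raise ValueError("predicted fragment size must be positive")
    return size


def assess_toxicity(n_dead: int, n_deformed: int, n_normal: int) -> ToxicityResult:
    """Score an injection dose: toxic when >50% dead and/or deformed."""
    if min(n_dead, n_deformed, n_normal) < 0:
        raise ValueError("counts must be non-negative")
    total = n_dead + n_deformed + n_normal
    if total == 0:
        raise ValueError("no embryos scored")
    frac = (n_dead + n_deformed) / total
    return ToxicityResult(n_dead, n_deformed, n_normal, frac, toxic=frac > 0.5)


def founder_mutation_totals(mutations_per_founder: list[int]) -> tuple[int, int]:
    """Totals for a founder cohort: (transmitting founders, mutations).

    ``mutations_per_founder`` lists, per germline-transmitting founder, how
    many distinct mutations it transmitted (e.g. four founders with one
    mutation each, one with two and one with three gives 6 founders and
    9 mutations).
    """
    if any(n < 1 for n in mutations_per_founder):
        raise ValueError("each transmitting founder carries >= 1 mutation")
    return len(mutations_per_founder), sum(mutations_per_founder)
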