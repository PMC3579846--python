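"""Seeded generators for every input the screening pipeline consumes.

The generators emulate the data a ZFN mutagenesis campaign produces:

* a synthetic genome contig with a composite target site embedded, plus the
  230-350 bp wild-type amplicon a primer pair would produce around it;
* NHEJ allele spectra at the cut site — insertions (most often a 4 bp
  duplication of the adjacent wild-type sequence), deletions up to tens of
  bp with a heavier large-size tail than insertions, and rarer complex
  events combining a deletion with insertion of random nucleotides;
* clone sets drawn from a true somatic lesion frequency;
* pooled-embryo fragment-analysis peak tables with multiplicative
  (lognormal) height noise and an optional non-templated +A artifact.

Every generator is a pure function of its arguments and seed: the same
call yields byte-identical output.  What is *not* modelled: chromatograms,
PCR amplification bias, allele dropout, or instrument sizing error beyond
the peak-height noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from zfnscreen.founders import Peak, PeakTable, PoolPlan
from zfnscreen.sites import TargetSpec

_BASES = np.array(list("ACGT"))

_DEFAULT_INS_SIZES = {1: 0.15, 2: 0.10, 3: 0.10, 4: 0.35, 5: 0.10,
                      6: 0.08, 7: 0.05, 8: 0.04, 9: 0.02, 10: 0.01}


def _default_del_sizes(max_del: int = 60, decay: float = 0.90) -> dict[int, float]:
    """Truncated geometric deletion-size distribution (heavy tail to max_del)."""
    w = {d: decay ** d for d in range(1, max_del + 1)}
    total = sum(w.values())
    return {d: v / total for d, v in w.items()}


@dataclass(frozen=True)
class IndelSpectrum:
    """NHEJ event spectrum at a nuclease cut site.

    Defaults are stylised to the qualitative facts of ZFN lesion data:
    the modal event is a +4 duplication insertion, deletions extend to
    tens of bp and dominate insertions beyond 10 bp, and complex events
    (deletion plus random-nucleotide insertion) are rare.
    """

    p_insertion: float = 0.45
    p_deletion: float = 0.45
    p_complex: float = 0.10
    insertion_size_dist: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_INS_SIZES))
    deletion_size_dist: dict[int, float] = field(
        default_factory=_default_del_sizes)
    p_duplication_given_insertion: float = 0.6

    def __post_init__(self) -> None:
        total = self.p_insertion + self.p_deletion + self.p_complex
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        for dist, name in ((self.insertion_size_dist, "insertion"),
                           (self.deletion_size_dist, "deletion")):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name}_size_dist does not sum to 1")
            if any(s < 1 for s in dist):
                raise ValueError(f"{name} sizes must be >= 1 bp")
        ins_tail = sum(p for s, p in self.insertion_size_dist.items() if s > 10)
        del_tail = sum(p for s, p in self.deletion_size_dist.items() if s > 10)
        if del_tail < ins_tail:
            raise ValueError("deletion tail beyond 10 bp must be at least "
                             "as heavy as the insertion tail")
        if not 0 <= self.p_duplication_given_insertion <= 1:
            raise ValueError("p_duplication_given_insertion outside [0, 1]")


@dataclass(frozen=True)
class SimAllele:
    """A simulated mutant allele with its truth label."""

    seq: str
    allele_class: str   # insertion | deletion | complex
    net_delta: int
    inserted_seq: str
    deleted_seq: str
    is_duplication: bool
    event_start: int    # as generated; classifiers may left-align


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass(frozen=True)
class Locus:
    """A synthetic locus: genome contig plus the wild-type amplicon."""

    contig_id: str
    contig_seq: str
    amplicon_id: str
    amplicon_seq: str
    site_start_in_contig: int
    site_start_in_amplicon: int
    left_len: int
    spacer_len: int
    right_len: int

    @property
    def site_len(self) -> int:
        return self.left_len + self.spacer_len + self.right_len

    @property
    def cut_pos(self) -> int:
        """Middle of the spacer, in amplicon coordinates."""
        return self.site_start_in_amplicon + self.left_len + self.spacer_len // 2

    @property
    def spacer_window(self) -> tuple[int, int]:
        """The spacer interval in amplicon coordinates (half-open)."""
        lo = self.site_start_in_amplicon + self.left_len
        return (lo, lo + self.spacer_len)

    def to_fasta(self) -> str:
        return (f">{self.contig_id}\n{self.contig_seq}\n"
                f">{self.amplicon_id}\n{self.amplicon_seq}\n")


def make_locus(seed: int, length: int, spec: TargetSpec,
               amplicon_range: tuple[int, int] = (230, 350)) -> Locus:
    """Random contig with ``spec`` embedded, and the amplicon around it.

    The amplicon length is drawn uniformly from ``amplicon_range`` (the
    usual 230-350 bp sizing window for fragment analysis) and the composite
    site centre is placed within +/-10% of the amplicon midpoint, as a
    primer designer would aim for.
    """
    rng = np.random.default_rng(seed)
    ll, lr = len(spec.left_site), len(spec.right_site)
    sp_lo, sp_hi = spec.spacer_len_range
    spacer_len = int(rng.integers(sp_lo, sp_hi + 1))
    site = spec.left_site + _random_seq(rng, spacer_len) + spec.right_site
    max_amp = amplicon_range[1]
    if length < len(site) + 2 * max_amp:
        raise ValueError(
            f"contig length {length} too short: need >= {len(site) + 2 * max_amp}")
    amp_len = int(rng.integers(amplicon_range[0], amplicon_range[1] + 1))
    centre_frac = rng.uniform(0.4, 0.6)
    site_centre_in_amp = int(round(amp_len * centre_frac))
    site_start_in_amp = site_centre_in_amp - len(site) // 2
    site_start_in_amp = max(1, min(site_start_in_amp, amp_len - len(site) - 1))
    site_start = int(rng.integers(max_amp, length - max_amp - len(site)))
    contig = (_random_seq(rng, site_start) + site
              + _random_seq(rng, length - site_start - len(site)))
    amp_start = site_start - site_start_in_amp
    amplicon = contig[amp_start:amp_start + amp_len]
    return Locus(
        contig_id=f"{spec.gene_id}_contig",
        contig_seq=contig,
        amplicon_id=f"{spec.gene_id}_amplicon",
        amplicon_seq=amplicon,
        site_start_in_contig=site_start,
        site_start_in_amplicon=site_start_in_amp,
        left_len=ll, spacer_len=spacer_len, right_len=lr,
    )


def _sample_dist(rng: np.random.Generator, dist: dict[int, float]) -> int:
    sizes = np.array(sorted(dist))
    probs = np.array([dist[s] for s in sizes], dtype=float)
    return int(rng.choice(sizes, p=probs / probs.sum()))


def simulate_alleles(
    wt: str,
    cut_pos: int,
    spectrum: IndelSpectrum,
    n: int,
    seed: int,
) -> list[SimAllele]:
    """Draw ``n`` mutant alleles by applying one NHEJ event at the cut.

    Insertions go in at ``cut_pos``; with probability
    ``p_duplication_given_insertion`` the inserted bases duplicate the
    wild-type sequence immediately 5' of the cut, otherwise they are
    random.  Deletions are centred on the cut.  Complex events delete and
    then insert random bases; the inserted bases are resampled so the
    event cannot collapse to a pure indel of the same sequence (first and
    last inserted base differ from the corresponding deleted base, and the
    insertion and deletion lengths differ).  Events that would run past
    the amplicon flanks are resampled.
    """
    wt = wt.upper()
    if not 0 < cut_pos < len(wt):
        raise ValueError("cut_pos must lie strictly inside the amplicon")
    rng = np.random.default_rng(seed)
    classes = np.array(["insertion", "deletion", "complex"])
    class_p = np.array([spectrum.p_insertion, spectrum.p_deletion,
                        spectrum.p_complex])
    out: list[SimAllele] = []
    margin = 20  # keep primer-anchored flanks intact
    while len(out) < n:
        klass = str(rng.choice(classes, p=class_p))
        if klass == "insertion":
            size = _sample_dist(rng, spectrum.insertion_size_dist)
            is_dup = (rng.random() < spectrum.p_duplication_given_insertion
                      and cut_pos - size >= margin)
            ins = (wt[cut_pos - size:cut_pos] if is_dup
                   else _random_seq(rng, size))
            seq = wt[:cut_pos] + ins + wt[cut_pos:]
            out.append(SimAllele(seq, "insertion", size, ins, "",
                                 is_dup, cut_pos))
        elif klass == "deletion":
            size = _sample_dist(rng, spectrum.deletion_size_dist)
            start = cut_pos - size // 2
            if start < margin or start + size > len(wt) - margin:
                continue  # event larger than the flank: resample
            deleted = wt[start:start + size]
            seq = wt[:start] + wt[start + size:]
            out.append(SimAllele(seq, "deletion", -size, "", deleted,
                                 False, start))
        else:
            dsize = _sample_dist(rng, spectrum.deletion_size_dist)
            isize = _sample_dist(rng, spectrum.insertion_size_dist)
            if isize == dsize:
                continue  # equal lengths would be substitution-like
            start = cut_pos - dsize // 2
            if start < margin or start + dsize > len(wt) - margin:
                continue
            deleted = wt[start:start + dsize]
            for _ in range(100):
                ins = _random_seq(rng, isize)
                if ins[0] != deleted[0] and ins[-1] != deleted[-1]:
                    break
            else:  # pragma: no cover - astronomically unlikely
                continue
            seq = wt[:start] + ins + wt[start + dsize:]
            out.append(SimAllele(seq, "complex", isize - dsize, ins,
                                 deleted, False, start))
    return out


def simulate_clone_set(
    wt: str,
    alleles: list[SimAllele],
    lesion_freq: float,
    n_clones: int,
    seed: int,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Draw a colony-PCR clone set at a true somatic lesion frequency.

    Each clone is wild type with probability ``1 - lesion_freq``,
    otherwise a uniformly chosen mutant allele.  Returns ``(records,
    truth)`` where records are ``(clone_id, sequence)`` pairs and truth
    rows carry the generating labels.
    """
    if not 0 <= lesion_freq <= 1:
        raise ValueError("lesion_freq must be in [0, 1]")
    if lesion_freq > 0 and not alleles:
        raise ValueError("need mutant alleles when lesion_freq > 0")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for i in range(n_clones):
        clone_id = f"clone_{i + 1:03d}"
        if rng.random() < lesion_freq:
            idx = int(rng.integers(0, len(alleles)))
            a = alleles[idx]
            records.append((clone_id, a.seq))
            truth.append({"clone_id": clone_id, "is_mutant": True,
                          "allele_index": idx, "allele_class": a.allele_class,
                          "net_delta": a.net_delta,
                          "is_duplication": a.is_duplication})
        else:
            records.append((clone_id, wt))
            truth.append({"clone_id": clone_id, "is_mutant": False,
                          "allele_index": -1, "allele_class": "WT",
                          "net_delta": 0, "is_duplication": False})
    return records, truth


@dataclass(frozen=True)
class ScreenSim:
    """Simulated pooled founder screen: peak tables plus the truth."""

    peak_tables: tuple[PeakTable, ...]
    wt_size: float
    plan: PoolPlan
    allele_deltas: tuple[int, ...]
    # truth[well_index][net_delta] = heterozygous embryos carrying it
    het_per_well: tuple[dict[int, int], ...]


def simulate_founder_screen(
    allele_freqs: dict[int, float],
    plan: PoolPlan,
    wt_size: float = 257.0,
    peak_noise_cv: float = 0.0,
    plus_a_artifact: bool = False,
    seed: int = 0,
    gain: float = 1000.0,
) -> ScreenSim:
    """Simulate one founder's pooled screen.

    ``allele_freqs`` maps each transmitted allele's net length change (bp)
    to its germline transmission frequency.  Each embryo is heterozygous
    for at most one allele (outcross to wild type); each well aggregates
    ``2 * pool_size`` alleles and every distinct fragment size yields one
    peak with height = allele count x gain x lognormal(mean 1, cv).  With
    ``plus_a_artifact`` each allele's product is split between its true
    size and a +1 bp shadow (incomplete non-templated adenylation without
    PIG-tailing) at a shadow/parent height ratio drawn uniformly in
    [0.3, 0.7]; the split conserves total signal, so merging the shadow
    back restores the artifact-free peak exactly.

    Embryo genotypes are drawn from a dedicated RNG stream, so runs that
    differ only in noise or artifact settings share genotypes.
    """
    if any(not 0 <= p <= 1 for p in allele_freqs.values()):
        raise ValueError("transmission frequencies must be in [0, 1]")
    if sum(allele_freqs.values()) > 1:
        raise ValueError("transmission frequencies sum to more than 1")
    if peak_noise_cv < 0:
        raise ValueError("peak_noise_cv must be >= 0")
    rng_geno = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(seed + 1_000_003)
    deltas = sorted(allele_freqs)
    cum = np.cumsum([allele_freqs[d] for d in deltas])
    sigma = np.sqrt(np.log1p(peak_noise_cv ** 2)) if peak_noise_cv > 0 else 0.0

    def noise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng_noise.lognormal(mean=-sigma ** 2 / 2, sigma=sigma))

    tables, het_per_well = [], []
    for w in range(plan.n_pools):
        counts: dict[float, float] = {}
        het: dict[int, int] = {}
        n_wt_alleles = 0
        for _ in range(plan.pool_size):
            u = rng_geno.random()
            idx = int(np.searchsorted(cum, u, side="right"))
            if idx < len(deltas):  # heterozygous embryo
                d = deltas[idx]
                het[d] = het.get(d, 0) + 1
                size = wt_size + d
                counts[size] = counts.get(size, 0) + 1
                n_wt_alleles += 1
            else:
                n_wt_alleles += 2
        counts[wt_size] = counts.get(wt_size, 0) + n_wt_alleles
        peaks: dict[float, float] = {}
        for size, n_alleles in counts.items():
            h = n_alleles * gain * noise()
            if plus_a_artifact:
                ratio = rng_noise.uniform(0.3, 0.7)
                peaks[size] = peaks.get(size, 0.0) + h / (1.0 + ratio)
                peaks[size + 1] = (peaks.get(size + 1, 0.0)
                                   + h * ratio / (1.0 + ratio))
            else:
                peaks[size] = peaks.get(size, 0.0) + h
        table = PeakTable(
            well_id=f"well_{w + 1:02d}",
            peaks=tuple(Peak(size=s, height=peaks[s])
                        for s in sorted(peaks)))
        tables.append(table)
        het_per_well.append(het)
    return ScreenSim(
        peak_tables=tuple(tables),
        wt_size=wt_size,
        plan=plan,
        allele_deltas=tuple(deltas),
        het_per_well=tuple(het_per_well),
    )
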