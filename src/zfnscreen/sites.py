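"""Target-site discovery and mismatch-tolerant off-target counting.

A zinc-finger nuclease (ZFN) pair recognises a composite site laid out as
``[left half-site][spacer][right half-site]`` on the genomic plus strand;
the FokI nuclease cuts inside the 5-7 bp spacer (up to 21 bp for
TALEN-style sites).  This module enumerates candidate composite sites in a
coding sequence, counts approximate matches of a query anywhere in a genome
on both strands (Hamming distance, no gaps), extends that scan to the paired
two-half-site geometry including homodimeric (left/left, right/right)
configurations, and checks candidate sites for polymorphisms across
re-sequenced individuals.

Coordinates are 0-based, half-open throughout; strand ``-`` matches are
reported at their plus-strand location (the window whose reverse complement
equals the query).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; N -> 4 (mismatches every base, including N)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str, allow_n: bool = True) -> str:
    allowed = set("ACGTN" if allow_n else "ACGT")
    up = seq.upper()
    bad = set(up) - allowed
    if bad:
        raise ValueError(
            f"{what} contains non-{'ACGTN' if allow_n else 'ACGT'} "
            f"characters: {sorted(bad)}"
        )
    return up


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGTN characters")
    return arr


@dataclass(frozen=True)
class TargetSpec:
    """A nuclease target site: left half-site, spacer, right half-site.

    ``cds_position`` is the 0-based offset of the first base of the left
    half-site within the coding sequence it was found in.
    """

    gene_id: str
    left_site: str
    spacer_len_range: tuple[int, int]
    right_site: str
    cds_position: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_site",
                           _validate_dna(self.left_site, "left_site", allow_n=False))
        object.__setattr__(self, "right_site",
                           _validate_dna(self.right_site, "right_site", allow_n=False))
        for name, site in (("left_site", self.left_site),
                           ("right_site", self.right_site)):
            if not 9 <= len(site) <= 18:
                raise ValueError(f"{name} must be 9-18 nt, got {len(site)}")
        lo, hi = self.spacer_len_range
        if not (1 <= lo <= hi <= 21):
            raise ValueError(f"spacer range {self.spacer_len_range} outside [1, 21]")
        if self.cds_position < 0:
            raise ValueError("cds_position must be >= 0")

    @property
    def site_len_range(self) -> tuple[int, int]:
        lo, hi = self.spacer_len_range
        n = len(self.left_site) + len(self.right_site)
        return (n + lo, n + hi)


@dataclass(frozen=True, order=True)
class GenomeMatch:
    """One approximate match of a query on a genome contig.

    ``start``/``end`` are 0-based half-open plus-strand coordinates;
    a ``-`` strand match means the reverse complement of the window equals
    the query within the mismatch budget.
    """

    contig: str
    start: int
    strand: str = field(compare=False)
    mismatches: int = field(compare=False)
    end: int = field(compare=False, default=0)

    @property
    def sort_key(self) -> tuple:
        return (self.contig, self.start, 0 if self.strand == "+" else 1)


@dataclass(frozen=True)
class PairedMatch:
    """A paired (dimeric) off-target locus.

    ``configuration`` is ``LR`` for the productive heterodimer (left
    half-site facing a right half-site across the spacer) or ``LL``/``RR``
    for homodimeric arrangements in which two copies of the same half-site
    converge on a spacer.
    """

    contig: str
    start: int
    end: int
    strand: str
    configuration: str  # LR | LL | RR
    left_mismatches: int
    right_mismatches: int
    spacer_len: int


@dataclass(frozen=True)
class SnpCheckResult:
    """Outcome of the SNP pre-screen of one candidate site.

    ``variant_positions`` are 0-based offsets within the composite site
    (0 = first base of the left half-site).  A site passes when no variant
    falls inside either half-site; spacer variants are reported but do not
    fail the site.
    """

    site_id: str
    variant_positions: tuple[int, ...]
    n_individuals: int
    passes: bool


def scan_candidate_sites(
    cds: str,
    left_len: int,
    right_len: int,
    spacer_range: tuple[int, int],
    first_half_only: bool = False,
    gene_id: str = "gene",
) -> list[TargetSpec]:
    """Enumerate every ``[left][spacer][right]`` window in a coding sequence.

    Windows are reported for every spacer length in ``spacer_range`` and
    ordered by start position (then spacer length).  With
    ``first_half_only`` set, only windows starting in the first half of the
    CDS (start < floor(len/2)) are returned — nuclease sites early in the
    open reading frame are preferred so that frameshifts truncate most of
    the protein.  Windows containing ``N`` are skipped.
    """
    cds = _validate_dna(cds, "cds")
    if left_len <= 0 or right_len <= 0:
        raise ValueError("half-site lengths must be positive")
    lo, hi = spacer_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid spacer range {spacer_range}")
    if len(cds) < left_len + lo + right_len:
        raise ValueError("cds shorter than the minimal composite window")
    limit = len(cds) // 2 if first_half_only else len(cds)
    out: list[TargetSpec] = []
    for start in range(len(cds)):
        if start >= limit:
            break
        for spacer in range(lo, hi + 1):
            end = start + left_len + spacer + right_len
            if end > len(cds):
                continue
            left = cds[start:start + left_len]
            right = cds[end - right_len:end]
            if "N" in left or "N" in right:
                continue
            out.append(TargetSpec(
                gene_id=gene_id,
                left_site=left,
                spacer_len_range=(spacer, spacer),
                right_site=right,
                cds_position=start,
            ))
    return out


def _scan_one_strand(contig_arr: np.ndarray, query_arr: np.ndarray,
                     k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Hamming scan: positions and mismatch counts with <= k."""
    n, m = len(contig_arr), len(query_arr)
    if n < m:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    nwin = n - m + 1
    mm = np.zeros(nwin, dtype=np.int32)
    for i in range(m):
        window = contig_arr[i:i + nwin]
        qb = query_arr[i]
        # N (code 4) in genome or query mismatches everything
        mm += ((window != qb) | (window == 4) | (qb == 4))
    hits = np.nonzero(mm <= k)[0]
    return hits, mm[hits]


def count_offtargets(
    genome: dict[str, str],
    query: str,
    k: int,
) -> list[GenomeMatch]:
    """All positions on both strands with Hamming distance <= ``k`` to query.

    ``genome`` maps contig names to sequences.  Matches are sorted by
    (contig, start, strand ``+`` before ``-``).  No gapped matching is
    attempted, and windows running off a contig end are not reported.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if k < 0:
        raise ValueError("mismatch budget k must be >= 0")
    if k >= len(query):
        raise ValueError(
            f"k={k} >= query length {len(query)}: every window would match")
    query = _validate_dna(query, "query")
    fwd = _encode(query)
    rev = _encode(revcomp(query))
    matches: list[GenomeMatch] = []
    for contig in sorted(genome):
        seq = _validate_dna(genome[contig], f"contig {contig}")
        arr = _encode(seq)
        for strand, qarr in (("+", fwd), ("-", rev)):
            hits, mms = _scan_one_strand(arr, qarr, k)
            for pos, mm in zip(hits.tolist(), mms.tolist()):
                matches.append(GenomeMatch(
                    contig=contig, start=pos, strand=strand,
                    mismatches=mm, end=pos + len(query)))
    matches.sort(key=lambda m: m.sort_key)
    return matches


def count_paired_offtargets(
    genome: dict[str, str],
    spec: TargetSpec,
    k_per_half: int,
    spacer_range: tuple[int, int] | None = None,
    allow_homodimer: bool = False,
) -> list[PairedMatch]:
    """Loci where two half-site matches converge across a valid spacer.

    A productive cut requires one FokI monomer on each side of the spacer.
    The left half-site is read on the plus strand toward the spacer; the
    right half-site as printed lies downstream on the plus strand (its
    monomer binds the minus strand facing back at the spacer).  Matches are
    therefore paired as:

    * ``LR`` '+': left-site plus-strand match, then right-site plus-strand
      match downstream across the spacer (the printed composite layout);
    * ``LR`` '-': the reverse complement of that composite;
    * ``LL``: a left-site plus-strand match facing a left-site minus-strand
      match (two left monomers converging), reported when
      ``allow_homodimer`` is set; likewise ``RR``.

    Homodimeric binding is what engineered heterodimeric FokI variants
    (EL/KK, ELD/KKR) are designed to suppress; counting those loci shows
    what the variants buy.
    """
    if spacer_range is None:
        spacer_range = spec.spacer_len_range
    lo, hi = spacer_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid spacer range {spacer_range}")
    left_hits = count_offtargets(genome, spec.left_site, k_per_half)
    right_hits = count_offtargets(genome, spec.right_site, k_per_half)
    ll, lr = len(spec.left_site), len(spec.right_site)

    def by_contig(hits, strand):
        d: dict[str, dict[int, int]] = {}
        for h in hits:
            if h.strand == strand:
                d.setdefault(h.contig, {})[h.start] = h.mismatches
        return d

    l_plus, l_minus = by_contig(left_hits, "+"), by_contig(left_hits, "-")
    r_plus, r_minus = by_contig(right_hits, "+"), by_contig(right_hits, "-")

    out: list[PairedMatch] = []

    def pair(up: dict, up_len: int, down: dict, down_len: int,
             config: str, strand: str, up_is_left: bool) -> None:
        for contig, starts in up.items():
            downs = down.get(contig, {})
            if not downs:
                continue
            for a, mm_up in starts.items():
                for sp in range(lo, hi + 1):
                    b = a + up_len + sp
                    mm_down = downs.get(b)
                    if mm_down is None:
                        continue
                    mm_l, mm_r = ((mm_up, mm_down) if up_is_left
                                  else (mm_down, mm_up))
                    if config in ("LL", "RR"):
                        mm_l, mm_r = mm_up, mm_down
                    out.append(PairedMatch(
                        contig=contig, start=a, end=b + down_len,
                        strand=strand, configuration=config,
                        left_mismatches=mm_l, right_mismatches=mm_r,
                        spacer_len=sp))

    # LR '+': printed composite left(+) ... right(+)
    pair(l_plus, ll, r_plus, lr, "LR", "+", up_is_left=True)
    # LR '-': revcomp composite = revcomp(right) ... revcomp(left)
    pair(r_minus, lr, l_minus, ll, "LR", "-", up_is_left=False)
    if allow_homodimer:
        # LL: left(+) facing revcomp(left); RR: revcomp(right) facing right(+)
        pair(l_plus, ll, l_minus, ll, "LL", "+", up_is_left=True)
        pair(r_minus, lr, r_plus, lr, "RR", "+", up_is_left=True)
    out.sort(key=lambda p: (p.contig, p.start, p.configuration, p.strand,
                            p.spacer_len))
    return out


def check_snps(
    spec: TargetSpec,
    individual_seqs: list[str],
    site_offset: int | None = None,
) -> SnpCheckResult:
    """SNP pre-screen of one site across re-sequenced individuals.

    ``individual_seqs`` are same-length amplicon sequences (one per
    individual, e.g. 8 adult fish of the injection line) covering the site.
    The composite site is located in the first sequence unless
    ``site_offset`` gives its start explicitly.  Columns with two or more
    distinct bases among individuals inside the composite site are reported
    (offsets relative to site start); the site fails only when a variant
    falls inside a half-site, since a polymorphism under a zinc-finger
    contact can abolish binding while spacer variants merely move the cut.
    """
    if not individual_seqs:
        raise ValueError("need at least one individual sequence")
    seqs = [_validate_dna(s, "individual sequence") for s in individual_seqs]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"individual sequences differ in length: {sorted(lengths)}")
    ll, lr = len(spec.left_site), len(spec.right_site)
    lo, hi = spec.spacer_len_range
    if site_offset is None:
        site_offset = -1
        ref = seqs[0]
        for sp in range(lo, hi + 1):
            probe_len = ll + sp + lr
            for start in range(len(ref) - probe_len + 1):
                if (ref[start:start + ll] == spec.left_site
                        and ref[start + ll + sp:start + probe_len] == spec.right_site):
                    site_offset = start
                    spacer_len = sp
                    break
            if site_offset >= 0:
                break
        if site_offset < 0:
            raise ValueError("composite site not found in the first individual")
    else:
        spacer_len = lo
    site_len = ll + spacer_len + lr
    if site_offset + site_len > len(seqs[0]):
        raise ValueError("site interval extends past the amplicon end")
    variants = []
    for col in range(site_len):
        bases = {s[site_offset + col] for s in seqs}
        bases.discard("N")
        if len(bases) >= 2:
            variants.append(col)
    in_half_site = [v for v in variants if v < ll or v >= ll + spacer_len]
    return SnpCheckResult(
        site_id=spec.gene_id,
        variant_positions=tuple(variants),
        n_individuals=len(seqs),
        passes=not in_half_site,
    )
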