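"""Ancient-DNA damage assessment from aligned reads.

Covers the read-level QC (mean base quality, ambiguous bases, PCR
duplicates), consensus pileup with per-site common/different counts, the
terminal deamination profile (C->T from the 5' end, G->A from the 3' end,
strand-aware) with a two-parameter geometric decay fit, the
nucleosome-footprint fragment-length distribution, and threshold-based SNV
calling (minimum depth, minimum alternate-supporting reads).

Coordinates are 0-based half-open internally; VCF output is 1-based.
Read sequences are stored in forward-reference orientation (SAM convention);
the ``strand`` field records the template strand for end-aware analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


def ndimage_uniform(x: np.ndarray, size: int) -> np.ndarray:
    """Moving average with zero padding at the edges; output length preserved."""
    return uniform_filter1d(x, size=size, mode="constant", cval=0.0)


logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "DamageProfile",
    "DamageFit",
    "FragmentLengthDistribution",
    "filter_reads",
    "build_pileup",
    "terminal_damage_profile",
    "fit_damage_model",
    "fragment_length_distribution",
    "call_snvs",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    """A gapless aligned read; sequence in forward-reference orientation."""

    id: str
    reference: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    sequence: str
    qualities: np.ndarray  # phred, one per base

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.sequence) != self.qualities.size:
            raise ValueError("sequence and qualities lengths differ")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_reads(
    reads: list[AlignedRead],
    min_mean_quality: float = 20.0,
    drop_n: bool = True,
    dedup: bool = True,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Quality-filter a read set.

    Removes reads whose mean base quality is strictly below
    ``min_mean_quality``, reads containing an ambiguous 'N', and collapses
    PCR duplicates (same reference, start, strand and length) to a single
    representative.  Returns the retained reads and per-class removal counts.
    """
    counts = {"input": len(reads), "low_quality": 0, "contains_n": 0, "duplicate": 0}
    seen: set[tuple] = set()
    kept: list[AlignedRead] = []
    for r in reads:
        if drop_n and ("N" in r.sequence or "n" in r.sequence):
            counts["contains_n"] += 1
            continue
        if r.qualities.size and r.qualities.mean() < min_mean_quality:
            counts["low_quality"] += 1
            continue
        if dedup:
            key = (r.reference, r.start, r.strand, r.length)
            if key in seen:
                counts["duplicate"] += 1
                continue
            seen.add(key)
        kept.append(r)
    counts["retained"] = len(kept)
    logger.info("filter_reads: %s", counts)
    return kept, counts


# ---------------------------------------------------------------------------
# Pileup and consensus
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def build_pileup(
    reads: list[AlignedRead],
    reference_length: int,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-site base counts, plurality consensus and common/different tallies.

    Consensus is the plurality base at each covered site; ties resolve to the
    reference base when it is among the tied (if a reference is given), else
    to the alphabetically first tied base, and the site is flagged ambiguous.
    ``n_common`` counts reads matching the consensus, ``n_different`` the
    rest; their sum is the depth at every site.
    """
    counts = np.zeros((reference_length, 5), dtype=np.int64)  # A C G T other
    for r in reads:
        for offset, base in enumerate(r.sequence):
            site = r.start + offset
            if site >= reference_length:
                break
            counts[site, _BASE_IDX.get(base.upper(), 4)] += 1

    depth = counts.sum(axis=1)
    covered = np.nonzero(depth)[0]
    rows = []
    for site in covered:
        c = counts[site, :4]
        best = int(c.max())
        tied = [b for b, n in zip(_BASES, c) if n == best and best > 0]
        ambiguous = len(tied) > 1
        if not tied:  # only 'other' bases observed
            consensus, n_common = "N", 0
            ambiguous = True
        elif ambiguous and reference is not None and reference[site].upper() in tied:
            consensus, n_common = reference[site].upper(), best
        else:
            consensus, n_common = tied[0], best
        rows.append(
            {
                "site": int(site),
                "depth": int(depth[site]),
                "A": int(c[0]), "C": int(c[1]), "G": int(c[2]), "T": int(c[3]),
                "other": int(counts[site, 4]),
                "consensus": consensus,
                "n_common": int(n_common),
                "n_different": int(depth[site] - n_common),
                "ambiguous": bool(ambiguous),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site", "depth", "A", "C", "G", "T", "other", "consensus",
                 "n_common", "n_different", "ambiguous"],
    )


# ---------------------------------------------------------------------------
# Terminal damage profile
# ---------------------------------------------------------------------------

@dataclass
class DamageProfile:
    """C->T frequency by distance from the 5' end and G->A by distance from
    the 3' end, with per-position opportunity counts (reference C resp. G)."""

    positions: np.ndarray
    ct5_freq: np.ndarray
    ct5_num: np.ndarray
    ct5_den: np.ndarray
    ga3_freq: np.ndarray
    ga3_num: np.ndarray
    ga3_den: np.ndarray


def terminal_damage_profile(
    reads: list[AlignedRead], reference: str, k: int = 25
) -> DamageProfile:
    """Strand-aware terminal substitution profile over the first ``k`` positions.

    For each read, both the read and its reference segment are oriented to
    the template strand (reverse-complemented for '-' reads) so that position
    0 is the molecule's own 5' terminus.  At 5' position i the denominator is
    the number of reads whose oriented reference base is C and the numerator
    those reading T there; symmetrically G->A from the 3' end.
    """
    max_len = max((r.length for r in reads), default=0)
    if max_len and k > max_len:
        warnings.warn(f"k={k} exceeds the longest read ({max_len}); profile truncated", stacklevel=2)
        k = max_len
    ct_num = np.zeros(k, dtype=np.int64)
    ct_den = np.zeros(k, dtype=np.int64)
    ga_num = np.zeros(k, dtype=np.int64)
    ga_den = np.zeros(k, dtype=np.int64)
    for r in reads:
        seg = reference[r.start : r.end]
        if len(seg) != r.length:
            continue  # read hangs off the reference end
        if r.strand == "+":
            oref, oread = seg.upper(), r.sequence.upper()
        else:
            oref, oread = revcomp(seg.upper()), revcomp(r.sequence.upper())
        kk = min(k, r.length)
        for i in range(kk):
            if oref[i] == "C":
                ct_den[i] += 1
                if oread[i] == "T":
                    ct_num[i] += 1
            j = r.length - 1 - i  # position i from the 3' end
            if oref[j] == "G":
                ga_den[i] += 1
                if oread[j] == "A":
                    ga_num[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct_freq = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan)
        ga_freq = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan)
    return DamageProfile(
        positions=np.arange(k), ct5_freq=ct_freq, ct5_num=ct_num, ct5_den=ct_den,
        ga3_freq=ga_freq, ga3_num=ga_num, ga3_den=ga_den,
    )


@dataclass
class DamageFit:
    """Geometric decay fit p(i) = delta0 * decay**i to a terminal profile."""

    delta0: float
    decay: float | None
    residual: float
    ok: bool
    n_positions: int = 0


def fit_damage_model(profile: DamageProfile, end: str = "5p") -> DamageFit:
    """Fit the two-parameter geometric decay to one end's substitution profile.

    Weighted least squares on log-frequencies.  The delta-method variance of
    log(num/den) under binomial sampling is ~(1 - f)/num, so positions are
    weighted by their observed substitution count; the fit is further
    restricted to the contiguous run of leading positions with at least one
    observed substitution, because beyond that run the expected counts are
    sub-unit and a single stray mismatch would dominate the log scale.
    Parameters are clipped to delta0 in [0, 1], decay in [0, 1).
    """
    if end == "5p":
        num, den, freq = profile.ct5_num, profile.ct5_den, profile.ct5_freq
    elif end == "3p":
        num, den, freq = profile.ga3_num, profile.ga3_den, profile.ga3_freq
    else:
        raise ValueError("end must be '5p' or '3p'")

    if (den > 0).sum() < 3:
        raise ValueError("need at least 3 positions with nonzero denominators")
    if num.sum() == 0:
        return DamageFit(delta0=0.0, decay=None, residual=0.0, ok=False, n_positions=0)

    usable = (num > 0) & (den > 0)
    run = 0
    while run < usable.size and usable[run]:
        run += 1
    if run < 2:
        # terminal-only damage: delta0 estimable, decay is not
        d0 = float(np.clip(freq[0] if usable[0] else 0.0, 0.0, 1.0))
        return DamageFit(delta0=d0, decay=None, residual=0.0, ok=False, n_positions=run)

    idx = np.arange(run)
    logf = np.log(freq[:run])
    w = np.sqrt(num[:run].astype(float))  # polyfit squares the weights
    slope, intercept = np.polyfit(idx, logf, 1, w=w)
    delta0 = float(np.clip(np.exp(intercept), 0.0, 1.0))
    decay = float(np.clip(np.exp(slope), 0.0, 1.0 - 1e-12))
    fitted = delta0 * decay**idx
    residual = float((den[:run] * (freq[:run] - fitted) ** 2).sum())
    return DamageFit(delta0=delta0, decay=decay, residual=residual, ok=True, n_positions=run)


# ---------------------------------------------------------------------------
# Fragment lengths
# ---------------------------------------------------------------------------

@dataclass
class FragmentLengthDistribution:
    histogram: pd.DataFrame  # bin_start, bin_center, count, smoothed
    modal_length: float
    nucleosome_peak: bool
    nucleosome_window: tuple[float, float]


def fragment_length_distribution(
    reads: list[AlignedRead],
    bin_width: int = 5,
    smooth_bins: int = 3,
    nucleosome_window: tuple[float, float] = (140.0, 180.0),
) -> FragmentLengthDistribution:
    """Binned, moving-average-smoothed fragment-length histogram.

    The modal length is the center of the bin maximizing the smoothed count;
    ``nucleosome_peak`` is true when that mode falls inside the
    mononucleosome window (the ~146 bp histone-octamer footprint plus
    linker).
    """
    if not reads:
        raise ValueError("need at least one read")
    lengths = np.array([r.length for r in reads])
    lo = (lengths.min() // bin_width) * bin_width
    hi = ((lengths.max() // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    smoothed = ndimage_uniform(counts.astype(float), smooth_bins)
    centers = edges[:-1] + bin_width / 2.0
    mode = float(centers[int(np.argmax(smoothed))])
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_center": centers, "count": counts, "smoothed": smoothed}
    )
    in_window = nucleosome_window[0] <= mode <= nucleosome_window[1]
    return FragmentLengthDistribution(
        histogram=hist, modal_length=mode, nucleosome_peak=bool(in_window),
        nucleosome_window=tuple(nucleosome_window),
    )


# ---------------------------------------------------------------------------
# SNV calling
# ---------------------------------------------------------------------------

def call_snvs(
    pileup: pd.DataFrame,
    reference: str,
    min_depth: int = 3,
    min_alt: int = 2,
) -> pd.DataFrame:
    """Threshold-based SNV calls from a pileup.

    A site is emitted iff depth >= ``min_depth`` and the count of the most
    frequent non-reference base >= ``min_alt`` (both boundaries inclusive).
    Multi-allelic sites report the top alternate only.
    """
    rows = []
    for rec in pileup.itertuples(index=False):
        if rec.depth < min_depth:
            continue
        ref_base = reference[rec.site].upper()
        alt_counts = {b: getattr(rec, b) for b in _BASES if b != ref_base}
        if not alt_counts:
            continue
        alt = max(sorted(alt_counts), key=lambda b: alt_counts[b])
        if alt_counts[alt] < min_alt:
            continue
        rows.append(
            {"site": int(rec.site), "ref": ref_base, "alt": alt,
             "depth": int(rec.depth), "alt_count": int(alt_counts[alt])}
        )
    return pd.DataFrame(rows, columns=["site", "ref", "alt", "depth", "alt_count"])
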