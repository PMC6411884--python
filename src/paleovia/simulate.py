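"""Synthetic data with known ground truth for every pipeline input class.

Four generators emulate the study's inputs: two-channel 3D+t nucleus image
stacks (Gaussian-blurred spheres, H2B plus damage-scaled gammaH2A.X),
DDI cohorts with development outcomes, peptide-spectrum-match tables with
controllable deamidation, extracted-ion-chromatogram traces as sums of
Gaussian peaks, and deaminated nucleosomal read sets with geometric
terminal-damage decay.  Every generator is deterministic given its seed and
returns the exact ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .adna import AlignedRead, revcomp
from .imaging import ImageStack
from .proteomics import XICTrace, format_modifications

__all__ = [
    "NucleusSpec",
    "ImageSimParams",
    "CohortSpec",
    "DamageSimParams",
    "gen_nucleus_stack",
    "gen_ddi_cohort",
    "gen_psm_table",
    "gen_xic_trace",
    "gen_ancient_reads",
    "random_reference",
]


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    centroid_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    h2b_brightness: float  # a.u. per voxel inside the sphere
    damage_level: float  # unitless >= 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.h2b_brightness < 0 or self.damage_level < 0:
            raise ValueError("brightness and damage level must be non-negative")


@dataclass
class ImageSimParams:
    grid_shape: tuple[int, int, int] = (24, 96, 96)  # voxels (z, y, x)
    voxel_size: tuple[float, float, float] = (2.0, 0.5, 0.5)  # um, matching
    # confocal z-stacks at 2 um plane spacing
    n_frames: int = 1
    nuclei: list[NucleusSpec] = field(default_factory=list)
    gamma_per_damage: float = 50.0  # gamma-channel a.u. per damage unit
    background: float = 20.0
    noise_sd: float = 2.0
    psf_sigma: float = 1.0  # voxels, isotropic blur
    repair_rate: float = 0.0  # damage units removed per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be non-negative")


def _sphere_mask(grid_shape, voxel_size, centroid_um, radius_um) -> np.ndarray:
    axes = [np.arange(n) * v for n, v in zip(grid_shape, voxel_size)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    cz, cy, cx = centroid_um
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_um**2


def gen_nucleus_stack(params: ImageSimParams) -> tuple[ImageStack, pd.DataFrame]:
    """Render nuclei as Gaussian-blurred spheres in both channels.

    The H2B channel carries each sphere at its brightness; the gammaH2A.X
    channel carries gamma_per_damage * damage_level.  Additive Gaussian noise
    only (no Poisson term), so the returned truth table holds the exact
    noise-free integrated signal of each nucleus per channel per frame.
    With a positive ``repair_rate`` the damage level declines linearly over
    frames (floored at zero), emulating repair during live imaging.
    """
    shape = tuple(params.grid_shape)
    margin_um = 3.0 * params.psf_sigma * min(params.voxel_size)
    for i, nuc in enumerate(params.nuclei):
        for c, n, v in zip(nuc.centroid_um, shape, params.voxel_size):
            if c - nuc.radius_um - margin_um < 0 or c + nuc.radius_um + margin_um > (n - 1) * v:
                raise ValueError(
                    f"nucleus {i} (centroid {nuc.centroid_um} um, radius {nuc.radius_um} um) "
                    "overlaps the image boundary; shrink it or move it inward"
                )

    rng = np.random.default_rng(params.seed)
    blurred = []
    for nuc in params.nuclei:
        mask = _sphere_mask(shape, params.voxel_size, nuc.centroid_um, nuc.radius_um)
        blurred.append(ndimage.gaussian_filter(mask.astype(float), params.psf_sigma))

    voxels = np.empty((params.n_frames, 2, *shape))
    truth_rows = []
    for t in range(params.n_frames):
        h2b = np.zeros(shape)
        gamma = np.zeros(shape)
        for i, (nuc, b) in enumerate(zip(params.nuclei, blurred)):
            damage_t = max(nuc.damage_level - params.repair_rate * t, 0.0)
            h2b += nuc.h2b_brightness * b
            gamma += params.gamma_per_damage * damage_t * b
            truth_rows.append(
                {"nucleus": i, "frame": t,
                 "centroid_z_um": nuc.centroid_um[0], "centroid_y_um": nuc.centroid_um[1],
                 "centroid_x_um": nuc.centroid_um[2], "radius_um": nuc.radius_um,
                 "damage_level": damage_t,
                 "h2b_signal": float(nuc.h2b_brightness * b.sum()),
                 "gamma_signal": float(params.gamma_per_damage * damage_t * b.sum())}
            )
        for c, img in enumerate((h2b, gamma)):
            noisy = img + params.background + rng.normal(0.0, params.noise_sd, shape)
            voxels[t, c] = np.clip(noisy, 0.0, None)
    truth = pd.DataFrame(
        truth_rows,
        columns=["nucleus", "frame", "centroid_z_um", "centroid_y_um", "centroid_x_um",
                 "radius_um", "damage_level", "h2b_signal", "gamma_signal"],
    )
    stack = ImageStack(voxels=voxels, channel_map={"h2b": 0, "gamma_h2ax": 1},
                       voxel_size=params.voxel_size)
    return stack, truth


# ---------------------------------------------------------------------------
# DDI cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Groups of embryos with per-group true-damage distributions.

    Each group is (name, n_embryos, damage_dist) where damage_dist is a tuple
    ('constant', v) | ('normal', mean, sd) | ('lognormal', mu, sigma) |
    ('gamma', shape, scale); normal draws are clipped at zero.
    """

    groups: list[tuple[str, int, tuple]]
    reference_group: str

    def __post_init__(self) -> None:
        names = [g[0] for g in self.groups]
        if self.reference_group not in names:
            raise ValueError(f"reference group {self.reference_group!r} not among groups")
        for name, n, _ in self.groups:
            if n < 1:
                raise ValueError(f"group {name!r} must have n >= 1")


def _draw_damage(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(n, float(dist[1]))
    if kind == "normal":
        return np.clip(rng.normal(dist[1], dist[2], n), 0.0, None)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], n)
    if kind == "gamma":
        return rng.gamma(dist[1], dist[2], n)
    raise ValueError(f"unknown damage distribution {kind!r}")


def gen_ddi_cohort(
    spec: CohortSpec,
    seed: int,
    gamma_per_damage: float = 400.0,
    h2b_mean: float = 5000.0,
    ratio_noise_sd: float = 0.05,
    outcome_midpoint: float = 2.0,
    outcome_slope: float = 2.0,
) -> pd.DataFrame:
    """Draw per-embryo raw channel signals and development outcomes.

    The raw gamma/H2B ratio is proportional to the true damage (with small
    multiplicative lognormal noise); the development outcome is Bernoulli
    with success probability logistic in damage, midpoint at damage = 2 —
    the DDI level beyond which development usually fails — and configurable
    slope.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, n, dist in spec.groups:
        damage = _draw_damage(dist, n, rng)
        h2b = rng.lognormal(np.log(h2b_mean), 0.2, n)
        ratio = gamma_per_damage / h2b_mean * damage * np.exp(rng.normal(0, ratio_noise_sd, n))
        gamma = ratio * h2b
        p_success = 1.0 / (1.0 + np.exp(outcome_slope * (damage - outcome_midpoint)))
        outcome = rng.random(n) < p_success
        for i in range(n):
            rows.append(
                {"group": name, "embryo": f"{name}_{i:03d}",
                 "gamma_signal": float(gamma[i]), "h2b_signal": float(h2b[i]),
                 "true_damage": float(damage[i]), "developed": bool(outcome[i])}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def gen_psm_table(
    n_peptides: int,
    spectra_per_peptide: int,
    per_residue_deamid_prob: float,
    seed: int,
    sample: str = "sample1",
    min_len: int = 8,
    max_len: int = 16,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random tryptic-looking peptides with independent per-spectrum deamidation.

    Each spectrum of a peptide deamidates every N/Q residue independently
    with ``per_residue_deamid_prob``; identification confidences are uniform
    on [80, 100].  The truth table flags, per peptide, whether any generated
    spectrum was deamidated — the ground truth for the "even once" counting
    rule — alongside whether the sequence contains N/Q at all.
    """
    if not 0.0 <= per_residue_deamid_prob <= 1.0:
        raise ValueError("per_residue_deamid_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AMINO_ACIDS))
    peptides = []
    seen = set()
    while len(peptides) < n_peptides:
        length = int(rng.integers(min_len, max_len + 1))
        pep = "".join(rng.choice(aa, size=length))
        if pep in seen:
            continue
        seen.add(pep)
        peptides.append(pep)

    psm_rows, truth_rows = [], []
    for pep in peptides:
        nq_idx = [i for i, a in enumerate(pep) if a in "NQ"]
        ever_deamidated = False
        for s in range(spectra_per_peptide):
            mods = []
            for i in nq_idx:
                if rng.random() < per_residue_deamid_prob:
                    mods.append((i, f"Deamidated({pep[i]})"))
            if mods:
                ever_deamidated = True
            psm_rows.append(
                {"sample": sample, "peptide": pep,
                 "modifications": format_modifications(mods),
                 "confidence": float(rng.uniform(80.0, 100.0))}
            )
        truth_rows.append({"peptide": pep, "has_nq": bool(nq_idx),
                           "deamidated": ever_deamidated})
    return pd.DataFrame(psm_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# XIC traces
# ---------------------------------------------------------------------------

def gen_xic_trace(
    peaks: list[tuple[str, float, float, float]],
    sampling_step: float = 0.01,
    time_range: tuple[float, float] | None = None,
    peptide: str | None = None,
    channels: tuple[str, ...] = ("nondeamidated", "deamidated_shifted"),
) -> XICTrace:
    """Sum-of-Gaussians chromatogram; peaks are (channel, rt min, area, width min).

    The time axis spans all peaks plus six widths of margin, so the numeric
    integral of each rendered peak conserves its requested area to well
    within 0.5%.
    """
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    for _, _, _, width in peaks:
        if width <= 0:
            raise ValueError("peak widths must be positive")
    if time_range is None:
        if peaks:
            lo = min(rt - 6 * w for _, rt, _, w in peaks)
            hi = max(rt + 6 * w for _, rt, _, w in peaks)
        else:
            lo, hi = 0.0, 1.0
        time_range = (lo, hi)
    t = np.arange(time_range[0], time_range[1] + sampling_step, sampling_step)
    if not np.all(np.diff(t) > 0):
        raise ValueError("degenerate time axis")
    traces = {ch: np.zeros_like(t) for ch in channels}
    for ch, rt, area, width in peaks:
        if ch not in traces:
            raise ValueError(f"unknown channel {ch!r}")
        traces[ch] += area / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / width) ** 2)
    return XICTrace(time=t, channels=traces, peptide=peptide)


# ---------------------------------------------------------------------------
# Ancient reads
# ---------------------------------------------------------------------------

@dataclass
class DamageSimParams:
    n_reads: int = 10_000
    delta0: float = 0.3  # 5'-terminal C->T probability
    decay: float = 0.5  # per-position geometric decay
    frag_length_mix: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(158.0, 8.0, 1.0)]  # mononucleosome footprint
    )
    mean_quality: float = 35.0
    quality_sd: float = 3.0
    min_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta0 <= 1.0:
            raise ValueError("delta0 must be in [0, 1]")
        if not 0.0 <= self.decay < 1.0:
            raise ValueError("decay must be in [0, 1)")
        w = sum(c[2] for c in self.frag_length_mix)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("fragment-length mixture weights must sum to 1")


def random_reference(length: int, seed: int, gc: float = 0.5) -> str:
    """Uniform-ish random reference sequence (FASTA-ready)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def gen_ancient_reads(
    reference: str, params: DamageSimParams
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate deaminated, nucleosome-sized fragments aligned to ``reference``.

    Fragment lengths are drawn from the Gaussian mixture, start positions
    uniformly, strands equiprobably.  On the template strand (the read's own
    5'->3' orientation) C->T is applied at position i with probability
    delta0 * decay**i and G->A symmetrically from the 3' end — the
    single-strand cytosine-deamination signature on both termini.  Stored
    sequences are in forward-reference orientation; truth records fragment
    length and damaged positions per read.
    """
    if not reference:
        raise ValueError("empty reference")
    ref = reference.upper()
    max_mean = max(m for m, _, _ in params.frag_length_mix)
    if len(ref) <= max_mean:
        raise ValueError("reference shorter than the longest fragment component mean")
    rng = np.random.default_rng(params.seed)
    means = np.array([c[0] for c in params.frag_length_mix])
    sds = np.array([c[1] for c in params.frag_length_mix])
    weights = np.array([c[2] for c in params.frag_length_mix])

    comp = rng.choice(len(means), size=params.n_reads, p=weights)
    lengths = np.rint(rng.normal(means[comp], sds[comp])).astype(int)
    lengths = np.clip(lengths, params.min_length, len(ref))

    reads, truth_rows = [], []
    for i in range(params.n_reads):
        L = int(lengths[i])
        start = int(rng.integers(0, len(ref) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seg = ref[start : start + L]
        oriented = seg if strand == "+" else revcomp(seg)
        bases = np.frombuffer(oriented.encode(), dtype="S1").astype("U1")
        pos = np.arange(L)
        p5 = params.delta0 * params.decay**pos
        p3 = params.delta0 * params.decay ** (L - 1 - pos)
        hit5 = (bases == "C") & (rng.random(L) < p5)
        hit3 = (bases == "G") & (rng.random(L) < p3)
        bases[hit5] = "T"
        bases[hit3] = "A"
        damaged = np.nonzero(hit5 | hit3)[0]
        oriented_damaged = "".join(bases)
        seq_fwd = oriented_damaged if strand == "+" else revcomp(oriented_damaged)
        quals = np.clip(
            np.rint(rng.normal(params.mean_quality, params.quality_sd, L)), 2, 41
        ).astype(int)
        reads.append(
            AlignedRead(id=f"read{i:06d}", reference="ref", start=start,
                        strand=strand, sequence=seq_fwd, qualities=quals)
        )
        truth_rows.append(
            {"id": f"read{i:06d}", "length": L, "start": start, "strand": strand,
             "n_damaged": int(damaged.size),
             "damaged_positions_5p": ";".join(map(str, damaged.tolist()))}
        )
    truth = pd.DataFrame(
        truth_rows, columns=["id", "length", "start", "strand", "n_damaged",
                             "damaged_positions_5p"],
    )
    return reads, truth
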