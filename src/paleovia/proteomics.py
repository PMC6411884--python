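"""Post-mortem protein deterioration scoring from peptide-spectrum matches
and extracted-ion chromatograms.

Deamidation of asparagine (N->D) and glutamine (Q->E) is a spontaneous,
non-enzymatic clock of protein aging.  Two quantifications are provided:

* a counting score over PSM tables — the fraction of distinct N/Q-containing
  peptide sequences for which a deamidated spectrum was ever observed;
* an XIC-based score — Gaussian decomposition of the +0.984 Da channel into
  an isotope-interference component (pinned to the non-deamidated peak's
  retention time and width, since one 13C adds +1.0034 Da, chromatographically
  inseparable from the deamidated mass) plus a genuinely deamidated component
  at its own retention time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy.optimize import curve_fit

from .stats import fisher_exact_outcome

__all__ = [
    "filter_psms",
    "parse_modifications",
    "format_modifications",
    "psm_is_deamidated",
    "deamidation_rates",
    "compare_deamidation",
    "deamidation_mass_shift",
    "isotopologue_spacing",
    "averagine_m1_ratio",
    "XICTrace",
    "PeakDecomposition",
    "decompose_xic",
]

PSM_COLUMNS = ("sample", "peptide", "modifications", "confidence")


# ---------------------------------------------------------------------------
# PSM-table scoring
# ---------------------------------------------------------------------------

def parse_modifications(spec: str) -> list[tuple[int, str]]:
    """Parse 'Name@idx;Name@idx' (0-based residue index) into [(idx, name), ...]."""
    if spec is None or (isinstance(spec, float) and np.isnan(spec)) or spec == "":
        return []
    out = []
    for token in str(spec).split(";"):
        token = token.strip()
        if not token:
            continue
        name, _, idx = token.rpartition("@")
        if not name:
            raise ValueError(f"malformed modification token {token!r}")
        out.append((int(idx), name))
    return out


def format_modifications(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{name}@{idx}" for idx, name in mods)


def psm_is_deamidated(peptide: str, modifications) -> bool:
    """True when any modification is a deamidation sitting on an N or Q residue."""
    if isinstance(modifications, str) or modifications is None or (
        isinstance(modifications, float) and np.isnan(modifications)
    ):
        modifications = parse_modifications(modifications)
    for idx, name in modifications:
        if idx < 0 or idx >= len(peptide):
            raise ValueError(f"modification index {idx} outside peptide {peptide!r}")
        if "deamid" in name.lower() and peptide[idx] in "NQ":
            return True
    return False


def filter_psms(records: pd.DataFrame, min_confidence: float = 95.0) -> pd.DataFrame:
    """Drop PSMs whose identification confidence is below ``min_confidence`` percent.

    The boundary is inclusive: a PSM at exactly the threshold is retained.
    """
    if records.empty:
        warnings.warn("empty PSM table", stacklevel=2)
        return records.copy()
    keep = records["confidence"].astype(float) >= min_confidence
    n_removed = int((~keep).sum())
    if n_removed:
        warnings.warn(f"rejected {n_removed} PSMs below {min_confidence}% confidence", stacklevel=2)
    return records.loc[keep].reset_index(drop=True)


def deamidation_rates(records: pd.DataFrame, grouping: str = "whole-sample") -> pd.DataFrame:
    """Per-sample (or per-protein) deamidation rate over distinct peptide sequences.

    Denominator: distinct peptide sequences containing at least one N or Q.
    Numerator: those sequences with at least one PSM carrying a deamidation
    on an N/Q residue — a sequence counts as deamidated when a deamidated
    version was identified even once.  Sequences without N/Q are excluded.
    Expects an already confidence-filtered table.
    """
    if grouping == "whole-sample":
        keys = ["sample"]
    elif grouping == "per-protein":
        if "protein" not in records.columns:
            raise ValueError("per-protein grouping requires a 'protein' column")
        keys = ["sample", "protein"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    if records.empty:
        warnings.warn("no PSMs to score", stacklevel=2)
        return pd.DataFrame(columns=keys + ["n_sequences_with_nq", "n_deamidated", "rate"])
    work = records.copy()
    work["_has_nq"] = work["peptide"].map(lambda p: any(a in "NQ" for a in p))
    work["_deam"] = [
        psm_is_deamidated(p, m) for p, m in zip(work["peptide"], work["modifications"])
    ]
    for key_vals, grp in work.groupby(keys, sort=True):
        nq = grp.loc[grp["_has_nq"]]
        seqs = nq["peptide"].unique()
        n_deam = int(nq.groupby("peptide")["_deam"].any().sum())
        rate = n_deam / len(seqs) if len(seqs) else float("nan")
        if not len(seqs):
            warnings.warn(f"group {key_vals!r} has no N/Q-containing sequences; rate undefined", stacklevel=2)
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(n_sequences_with_nq=len(seqs), n_deamidated=n_deam, rate=rate)
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_deamidation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Fisher exact comparison of two deamidation rates; (odds ratio, two-sided p)."""
    for r in (a, b):
        if r["n_sequences_with_nq"] == 0:
            raise ValueError("rate undefined (zero denominator)")
    table = [
        [int(a["n_deamidated"]), int(a["n_sequences_with_nq"] - a["n_deamidated"])],
        [int(b["n_deamidated"]), int(b["n_sequences_with_nq"] - b["n_deamidated"])],
    ]
    return fisher_exact_outcome(table, alternative="two-sided")


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def _monoiso(element: str) -> float:
    return _ptmass.nist_mass[element][0][0]


def deamidation_mass_shift() -> float:
    """Monoisotopic mass shift of N->D / Q->E deamidation (replace NH2 by OH), Da."""
    return (_monoiso("O") + _monoiso("H")) - (_monoiso("N") + 2 * _monoiso("H"))


def isotopologue_spacing() -> float:
    """Mass added by one 12C -> 13C substitution, Da."""
    return _ptmass.nist_mass["C"][13][0] - _ptmass.nist_mass["C"][12][0]


# natural isotope abundance ratios (heavy/light) for the M+1 envelope
_M1_RATIO = {"C": 0.0107 / 0.9893, "H": 0.000115 / 0.999885, "N": 0.00364 / 0.99636, "O": 0.00038 / 0.99757, "S": 0.0075 / 0.9499}
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254


def averagine_m1_ratio(monoisotopic_mass: float | None = None, peptide: str | None = None) -> float:
    """Expected M+1/M intensity ratio of the first isotopologue peak.

    From the exact elemental composition when ``peptide`` is given, else from
    the averagine average-residue approximation at ``monoisotopic_mass``.
    """
    if peptide is not None:
        comp = _ptmass.Composition(sequence=peptide)
        counts = {el: comp.get(el, 0) for el in _M1_RATIO}
    else:
        if monoisotopic_mass is None:
            raise ValueError("give a peptide sequence or a monoisotopic mass")
        n_res = monoisotopic_mass / _AVERAGINE_MASS
        counts = {el: n_res * frac for el, frac in _AVERAGINE.items()}
    return float(sum(counts[el] * _M1_RATIO[el] for el in counts))


# ---------------------------------------------------------------------------
# XIC decomposition
# ---------------------------------------------------------------------------

@dataclass
class XICTrace:
    """Extracted-ion-chromatogram traces for the non-deamidated peptide mass
    and the +0.984 Da shifted mass, on a shared retention-time axis (min)."""

    time: np.ndarray
    channels: dict[str, np.ndarray]  # {"nondeamidated": ..., "deamidated_shifted": ...}
    peptide: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 3:
            raise ValueError("time axis must be 1-D with at least 3 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, y in self.channels.items():
            if y.shape != self.time.shape:
                raise ValueError(f"channel {name!r} length differs from time axis")


@dataclass
class PeakDecomposition:
    nondeam_area: float
    isotope_interference_area: float
    deamidated_area: float
    deamidated_fraction: float  # NaN when unresolved
    nondeam_rt: float
    nondeam_width: float
    deamidated_rt: float | None
    deamidated_width: float | None
    resolved: bool
    fraction_bounds: tuple[float, float] | None = None
    expected_interference_ratio: float | None = None
    interference_consistent: bool | None = None
    residual: float = 0.0
    extras: dict = field(default_factory=dict)


def gaussian_peak(t: np.ndarray, area: float, rt: float, width: float) -> np.ndarray:
    """Area-parameterized Gaussian chromatographic peak (width = sigma, min)."""
    return area / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / width) ** 2)


def emg_peak(t: np.ndarray, area: float, rt: float, width: float, tau: float) -> np.ndarray:
    """Exponentially modified Gaussian, for tailing peaks."""
    from scipy.special import erfc

    arg = (width / tau - (t - rt) / width) / np.sqrt(2)
    return (
        area / (2 * tau) * np.exp(width**2 / (2 * tau**2) - (t - rt) / tau) * erfc(arg)
    )


def _fit_single_gaussian(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i = int(np.argmax(y))
    area0 = max(float(np.trapezoid(y, t)), 1e-12)
    rt0 = float(t[i])
    width0 = max(area0 / (max(y[i], 1e-12) * np.sqrt(2 * np.pi)), (t[1] - t[0]))
    try:
        popt, _ = curve_fit(
            gaussian_peak, t, y, p0=[area0, rt0, width0],
            bounds=([0, t[0], (t[1] - t[0]) / 4], [np.inf, t[-1], t[-1] - t[0]]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"non-deamidated peak fit did not converge: {err}") from err
    return float(popt[0]), float(popt[1]), float(popt[2])


def decompose_xic(
    trace: XICTrace,
    charge: int = 2,
    model: str = "gaussian",
    min_separation_widths: float = 1.0,
) -> PeakDecomposition:
    """Separate the +0.984 Da channel into isotope interference and true deamidation.

    The non-deamidated channel is fit with one Gaussian.  The shifted channel
    is then modelled as an interference Gaussian constrained to that peak's
    retention time and width (free amplitude only — the M+1 isotopologue
    co-elutes perfectly with its parent) plus a free Gaussian for the
    deamidated peptide at its own retention time.  The deamidated area is the
    free component's.  When the fitted retention times are closer than
    ``min_separation_widths`` fitted widths the decomposition is flagged
    unresolved and only bounds on the deamidated fraction are reported.
    """
    if model not in ("gaussian", "emg"):
        raise ValueError("model must be 'gaussian' or 'emg'")
    t = trace.time
    y_n = trace.channels["nondeamidated"]
    y_d = trace.channels["deamidated_shifted"]
    if y_n.max() <= 0:
        raise ValueError("no resolvable peak in the non-deamidated channel")

    a_n, rt_n, w_n = _fit_single_gaussian(t, y_n)

    expected_ratio = None
    if trace.peptide is not None:
        expected_ratio = averagine_m1_ratio(peptide=trace.peptide)

    d_total = float(np.trapezoid(y_d, t))
    if d_total <= 1e-9 * max(a_n, 1.0) or y_d.max() <= 0:
        # flat shifted channel: nothing deamidated, nothing interfering
        return PeakDecomposition(
            nondeam_area=a_n, isotope_interference_area=0.0, deamidated_area=0.0,
            deamidated_fraction=0.0, nondeam_rt=rt_n, nondeam_width=w_n,
            deamidated_rt=None, deamidated_width=None, resolved=True,
            expected_interference_ratio=expected_ratio,
        )

    # initial interference amplitude from the shifted channel's height at rt_n
    interp_at_rtn = float(np.interp(rt_n, t, y_d))
    a_i0 = min(max(interp_at_rtn * w_n * np.sqrt(2 * np.pi), 0.0), d_total)
    resid0 = y_d - gaussian_peak(t, a_i0, rt_n, w_n)
    away = np.abs(t - rt_n) > min_separation_widths * w_n
    has_distinct = away.any() and resid0[away].max() > 0.05 * y_d.max()

    if not has_distinct:
        # co-elution: cannot chromatographically separate deamidation from M+1
        hi = d_total / (d_total + a_n) if (d_total + a_n) > 0 else 0.0
        return PeakDecomposition(
            nondeam_area=a_n, isotope_interference_area=float("nan"),
            deamidated_area=float("nan"), deamidated_fraction=float("nan"),
            nondeam_rt=rt_n, nondeam_width=w_n, deamidated_rt=None,
            deamidated_width=None, resolved=False, fraction_bounds=(0.0, hi),
            expected_interference_ratio=expected_ratio,
        )

    rt_d0 = float(t[away][np.argmax(resid0[away])])
    a_d0 = max(d_total - a_i0, 0.01 * d_total)

    if model == "gaussian":
        def two_comp(tt, a_i, a_d, rt_d, w_d):
            return gaussian_peak(tt, a_i, rt_n, w_n) + gaussian_peak(tt, a_d, rt_d, w_d)

        p0 = [a_i0, a_d0, rt_d0, w_n]
        lb = [0, 0, t[0], (t[1] - t[0]) / 4]
        ub = [np.inf, np.inf, t[-1], t[-1] - t[0]]
    else:
        def two_comp(tt, a_i, a_d, rt_d, w_d, tau):
            return gaussian_peak(tt, a_i, rt_n, w_n) + emg_peak(tt, a_d, rt_d, w_d, tau)

        p0 = [a_i0, a_d0, rt_d0, w_n, w_n / 2]
        lb = [0, 0, t[0], (t[1] - t[0]) / 4, 1e-4]
        ub = [np.inf, np.inf, t[-1], t[-1] - t[0], t[-1] - t[0]]

    try:
        popt, _ = curve_fit(two_comp, t, y_d, p0=p0, bounds=(lb, ub), maxfev=40_000)
    except RuntimeError as err:
        raise RuntimeError(
            f"shifted-channel fit did not converge (residual of initial guess: "
            f"{np.abs(y_d - two_comp(t, *p0)).sum():.3g}): {err}"
        ) from err
    a_i, a_d, rt_d, w_d = (float(v) for v in popt[:4])
    residual = float(((y_d - two_comp(t, *popt)) ** 2).sum())

    if abs(rt_d - rt_n) < min_separation_widths * max(w_n, w_d):
        hi = d_total / (d_total + a_n) if (d_total + a_n) > 0 else 0.0
        return PeakDecomposition(
            nondeam_area=a_n, isotope_interference_area=a_i, deamidated_area=a_d,
            deamidated_fraction=float("nan"), nondeam_rt=rt_n, nondeam_width=w_n,
            deamidated_rt=rt_d, deamidated_width=w_d, resolved=False,
            fraction_bounds=(0.0, hi), expected_interference_ratio=expected_ratio,
            residual=residual,
        )

    frac = a_d / (a_d + a_n) if (a_d + a_n) > 0 else 0.0
    consistent = None
    if expected_ratio is not None and a_n > 0:
        observed_ratio = a_i / a_n
        consistent = bool(0.5 * expected_ratio <= observed_ratio <= 2.0 * expected_ratio)
    return PeakDecomposition(
        nondeam_area=a_n, isotope_interference_area=a_i, deamidated_area=a_d,
        deamidated_fraction=frac, nondeam_rt=rt_n, nondeam_width=w_n,
        deamidated_rt=rt_d, deamidated_width=w_d, resolved=True,
        expected_interference_ratio=expected_ratio, interference_consistent=consistent,
        residual=residual,
    )
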