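"""Synthetic phantom and cohort generator.

Produces echo series, multi-TE spectra, and a histology-annotated cohort with
the statistical structure the downstream analysis assumes, so every stage is
testable without patient data. The default cohort mirrors the study design it
emulates: 73 type-2-diabetic subjects with steatosis grade counts
(6, 35, 11, 21) for none/mild/moderate/severe, grade-conditional PDFF medians
(0.12, 4.98, 10.84, 18.26)% drawn from truncated log-normal distributions,
~37% steatohepatitis, fibrosis stage counts (52, 12, 6, 2, 1) for F0-F4.

Within each grade the histology percentage (a multiple of 5 inside the
grade's band) and the true PDFF are comonotone: both are driven by the same
latent uniform, so their within-grade rank correlation is positive by
construction. All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import lognorm

from .gre_pdff import EchoSeries
from .histology import FIBROSIS_STAGES, GRADES, grade_steatosis
from .mrs_pdff import MULTI_TE_MS, SINGLE_TE_MS, SpectrumRecord, SpectrumSeries
from .spectral_model import (
    AcquisitionProtocol,
    FatSpectrum,
    TissueState,
    default_fat_spectrum,
    fat_modulation,
    ppm_to_hz,
)

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "simulate_cohort",
    "simulate_gre_series",
    "simulate_press_spectrum",
    "simulate_mrs_series",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_gre_series_csv",
    "read_gre_series_csv",
    "write_mrs_series",
    "read_mrs_series",
]

#: Histology bands per grade as (low, high) multiples of 5 consistent with
#: the grading convention (33 -> moderate, 66 -> moderate).
_GRADE_BANDS_PCT = {
    "none": (0, 0),
    "mild": (5, 30),
    "moderate": (35, 65),
    "severe": (70, 100),
}

#: Upper truncation of the grade-conditional PDFF distribution, percent.
_PDFF_TRUNCATION_PCT = 60.0

#: Default per-peak T2 of fat resonances at 3 T, ms.
DEFAULT_FAT_T2_MS = 60.0
#: Default water T2 at 3 T, ms.
DEFAULT_WATER_T2_MS = 25.0


def _check_probs(name: str, p: Sequence[float], length: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be nonnegative and sum to 1")
    return arr


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study population; medians are the
    spectroscopy grade-conditional medians (percent PDFF).
    """

    n_subjects: int = 73
    grade_proportions: tuple[float, ...] = (6 / 73, 35 / 73, 11 / 73, 21 / 73)
    grade_pdff_medians: tuple[float, ...] = (0.12, 4.98, 10.84, 18.26)
    pdff_dispersion: float = 0.45
    steatohepatitis_prob_by_grade: tuple[float, ...] = (0.0, 0.25, 0.5, 0.6)
    fibrosis_stage_probs: tuple[float, ...] = (52 / 73, 12 / 73, 6 / 73, 2 / 73, 1 / 73)
    noise_snr: float = 60.0
    seed: int = 0
    siderosis_prob: float = 2 / 73

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        _check_probs("grade_proportions", self.grade_proportions, 4)
        _check_probs("fibrosis_stage_probs", self.fibrosis_stage_probs, 5)
        med = self.grade_pdff_medians
        if len(med) != 4 or any(b <= a for a, b in zip(med, med[1:])):
            raise ValueError("grade_pdff_medians must be 4 strictly increasing values")
        if len(self.steatohepatitis_prob_by_grade) != 4 or any(
            not 0 <= p <= 1 for p in self.steatohepatitis_prob_by_grade
        ):
            raise ValueError("steatohepatitis probabilities must be 4 values in [0,1]")
        if self.pdff_dispersion <= 0 or self.noise_snr <= 0:
            raise ValueError("dispersion and SNR must be positive")


@dataclass
class SyntheticSubject:
    """One simulated subject: ground truth, histology, and tissue state."""

    subject_id: str
    true_pdff_percent: float
    histology_steatosis_percent: float
    grade: str
    steatohepatitis: bool
    fibrosis_stage: str
    tissue: TissueState
    siderosis: bool = False
    linewidth_hz: float = 45.0

    def __post_init__(self) -> None:
        if self.true_pdff_percent < 0:
            raise ValueError("true PDFF must be nonnegative")
        if self.histology_steatosis_percent % 5 != 0:
            raise ValueError("histology percent must be a multiple of 5")
        if grade_steatosis(self.histology_steatosis_percent) != self.grade:
            raise ValueError("histology percent inconsistent with grade")
        if self.fibrosis_stage not in FIBROSIS_STAGES:
            raise ValueError(f"unknown fibrosis stage {self.fibrosis_stage!r}")


def _truncated_lognormal_pdff(u: float, median: float, sigma: float) -> float:
    """Monotone map from a uniform draw to a log-normal PDFF truncated at 60%."""
    dist = lognorm(s=sigma, scale=median)
    u_trunc = u * dist.cdf(_PDFF_TRUNCATION_PCT)
    # guard against u == 0 exactly
    u_trunc = min(max(u_trunc, 1e-12), 1 - 1e-12)
    return float(dist.ppf(u_trunc))


def _histology_from_band(u: float, grade: str) -> float:
    lo, hi = _GRADE_BANDS_PCT[grade]
    pct = lo + u * (hi - lo)
    return float(np.clip(5 * round(pct / 5), lo, hi))


def simulate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw a reproducible synthetic cohort from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed)
    props = np.asarray(spec.grade_proportions)
    grade_idx = rng.choice(4, size=spec.n_subjects, p=props)
    subjects: list[SyntheticSubject] = []
    for i in range(spec.n_subjects):
        g = int(grade_idx[i])
        grade = GRADES[g]
        u = float(rng.uniform())
        pdff = _truncated_lognormal_pdff(u, spec.grade_pdff_medians[g],
                                         spec.pdff_dispersion)
        histo = _histology_from_band(u, grade)
        nash = bool(rng.random() < spec.steatohepatitis_prob_by_grade[g])
        fibrosis = FIBROSIS_STAGES[int(rng.choice(5, p=np.asarray(spec.fibrosis_stage_probs)))]
        siderosis = bool(rng.random() < spec.siderosis_prob)
        t2star = float(np.clip(rng.normal(20.0, 3.0), 12.0, 32.0))
        linewidth = float(rng.uniform(40.0, 50.0))
        spectrum = default_fat_spectrum()
        tissue = TissueState(
            water_density=100.0 - pdff,
            fat_density=pdff,
            t2star_ms=t2star,
            water_t2_ms=DEFAULT_WATER_T2_MS,
            per_peak_t2_ms={ppm: DEFAULT_FAT_T2_MS for ppm, _ in spectrum.peaks},
        )
        subjects.append(
            SyntheticSubject(
                subject_id=f"subj_{i + 1:03d}",
                true_pdff_percent=pdff,
                histology_steatosis_percent=histo,
                grade=grade,
                steatohepatitis=nash,
                fibrosis_stage=fibrosis,
                tissue=tissue,
                siderosis=siderosis,
                linewidth_hz=linewidth,
            )
        )
    return subjects


def simulate_gre_series(
    subject: SyntheticSubject,
    protocol: AcquisitionProtocol,
    snr: float,
    seed: int,
    spectrum: FatSpectrum | None = None,
    sigma: float | None = None,
) -> EchoSeries:
    """Rician-noisy magnitude echo series for one subject.

    Complex Gaussian noise of per-channel std ``sigma`` is added to the
    noise-free complex signal before taking the magnitude. By default
    ``sigma`` is the noise-free first-echo amplitude at the subject's total
    proton density divided by ``snr``.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    spectrum = spectrum or default_fat_spectrum()
    tissue = subject.tissue
    te = np.asarray(protocol.echo_times_ms)
    c = np.array([fat_modulation(t, spectrum, protocol.field_strength_T) for t in te])
    signal = (tissue.water_density + tissue.fat_density * c) * np.exp(
        -te / tissue.t2star_ms
    )
    if sigma is None:
        total = tissue.water_density + tissue.fat_density
        sigma = total * float(np.exp(-te[0] / tissue.t2star_ms)) / snr
    rng = np.random.default_rng(seed)
    noise = sigma * (rng.standard_normal(len(te)) + 1j * rng.standard_normal(len(te)))
    magnitudes = np.abs(signal + noise)
    return EchoSeries(roi_means=magnitudes, protocol=protocol, noise_sigma=sigma)


def simulate_press_spectrum(
    subject: SyntheticSubject,
    te_ms: float,
    spectrum: FatSpectrum | None = None,
    n_points: int = 1024,
    sweep_hz: float = 2000.0,
    linewidth_hz: float | None = None,
    n_averages: int = 2,
    snr: float = 90.0,
    seed: int = 0,
    field_T: float = 3.0,
) -> SpectrumRecord:
    """One complex FID at echo time ``te_ms``.

    Each resonance contributes ``rho_p exp(-TE/T2_p) exp((i 2 pi df_p -
    pi lw) t)`` with a Lorentzian lineshape of FWHM ``lw`` (the subject's
    shim linewidth, shared by water and fat). Complex Gaussian noise is
    scaled by ``1/sqrt(n_averages)``.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    if sweep_hz <= 0:
        raise ValueError("sweep width must be positive")
    spectrum = spectrum or default_fat_spectrum()
    lw = subject.linewidth_hz if linewidth_hz is None else linewidth_hz
    if lw <= 0:
        raise ValueError("linewidth must be positive")
    tissue = subject.tissue
    t = np.arange(n_points) / sweep_hz
    fid = tissue.water_density * np.exp(-te_ms / tissue.water_t2_ms) * np.exp(-np.pi * lw * t)
    for ppm, amp in spectrum.peaks:
        t2 = tissue.per_peak_t2_ms.get(ppm, DEFAULT_FAT_T2_MS)
        df = ppm_to_hz(ppm, field_T, spectrum.water_shift_ppm)
        fid = fid + (
            tissue.fat_density * amp * np.exp(-te_ms / t2)
            * np.exp((2j * np.pi * df - np.pi * lw) * t)
        )
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = (tissue.water_density + tissue.fat_density) / snr / np.sqrt(n_averages)
        fid = fid + sigma * (rng.standard_normal(n_points)
                             + 1j * rng.standard_normal(n_points))
    return SpectrumRecord(te_ms=float(te_ms), fid=fid, n_averages=n_averages)


def simulate_mrs_series(
    subject: SyntheticSubject,
    spectrum: FatSpectrum | None = None,
    multi_te_ms: Sequence[float] = MULTI_TE_MS,
    single_te_ms: float = SINGLE_TE_MS,
    n_points: int = 1024,
    sweep_hz: float = 2000.0,
    n_averages_multi: int = 2,
    n_averages_single: int = 40,
    snr: float = 90.0,
    seed: int = 0,
    field_T: float = 3.0,
) -> SpectrumSeries:
    """Full PRESS protocol for one subject: eight 2-average multi-TE records
    (TE 40--110 ms, TR 2000 ms) plus a 40-average single-echo record
    (TE 40 ms, TR 4000 ms)."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(multi_te_ms) + 1)
    records = [
        simulate_press_spectrum(
            subject, te, spectrum, n_points, sweep_hz, None,
            n_averages_multi, snr, _seed_int(child[i]), field_T,
        )
        for i, te in enumerate(multi_te_ms)
    ]
    single = simulate_press_spectrum(
        subject, single_te_ms, spectrum, n_points, sweep_hz, None,
        n_averages_single, snr, _seed_int(child[-1]), field_T,
    )
    return SpectrumSeries(
        records=records, sweep_hz=sweep_hz, n_points=n_points,
        tr_ms=2000.0, single_echo=single, single_echo_tr_ms=4000.0,
    )


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# --- cohort CSV spine -----------------------------------------------------

_COHORT_COLUMNS = [
    "subject_id", "true_pdff_pct", "histo_pct", "grade",
    "nash_flag", "fibrosis_stage", "siderosis_flag",
]


def cohort_to_frame(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "true_pdff_pct": [s.true_pdff_percent for s in subjects],
            "histo_pct": [s.histology_steatosis_percent for s in subjects],
            "grade": [s.grade for s in subjects],
            "nash_flag": [int(s.steatohepatitis) for s in subjects],
            "fibrosis_stage": [s.fibrosis_stage for s in subjects],
            "siderosis_flag": [int(s.siderosis) for s in subjects],
        }
    )


def write_cohort_csv(subjects_or_frame, path: str | Path) -> None:
    """Write the cohort table (one row per subject) to CSV."""
    if isinstance(subjects_or_frame, pd.DataFrame):
        frame = subjects_or_frame
    else:
        frame = cohort_to_frame(subjects_or_frame)
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises naming the offending row."""
    frame = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    for idx, row in frame.iterrows():
        if row["grade"] not in GRADES:
            raise ValueError(f"row {idx}: unknown grade {row['grade']!r}")
        if row["fibrosis_stage"] not in FIBROSIS_STAGES:
            raise ValueError(
                f"row {idx}: fibrosis stage {row['fibrosis_stage']!r} out of range"
            )
        if not (0 <= row["histo_pct"] <= 100) or row["histo_pct"] % 5 != 0:
            raise ValueError(f"row {idx}: invalid histology percent {row['histo_pct']}")
        if grade_steatosis(row["histo_pct"]) != row["grade"]:
            raise ValueError(
                f"row {idx}: grade {row['grade']!r} inconsistent with "
                f"{row['histo_pct']}%"
            )
        if row["true_pdff_pct"] < 0:
            raise ValueError(f"row {idx}: negative true PDFF")
    return frame


# --- echo-series CSV (long form) -----------------------------------------


def write_gre_series_csv(
    series_by_subject: dict[str, dict[str, EchoSeries]], path: str | Path
) -> None:
    """Long-form CSV: subject_id, protocol, te_ms, roi_mean, noise_sigma."""
    rows = []
    for sid, by_label in series_by_subject.items():
        for label, series in by_label.items():
            for te, m in zip(series.protocol.echo_times_ms, series.roi_means):
                rows.append(
                    {
                        "subject_id": sid,
                        "protocol": label,
                        "te_ms": te,
                        "roi_mean": m,
                        "noise_sigma": series.noise_sigma,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gre_series_csv(path: str | Path) -> dict[str, dict[str, EchoSeries]]:
    from .spectral_model import multi_echo_protocol, triple_echo_protocol

    frame = pd.read_csv(path)
    protocols = {"triple": triple_echo_protocol(), "multi": multi_echo_protocol()}
    out: dict[str, dict[str, EchoSeries]] = {}
    for (sid, label), grp in frame.groupby(["subject_id", "protocol"], sort=False):
        proto = protocols.get(label)
        if proto is None:
            raise ValueError(f"unknown protocol label {label!r} for subject {sid}")
        grp = grp.sort_values("te_ms")
        if not np.allclose(grp["te_ms"].to_numpy(), proto.echo_times_ms):
            raise ValueError(f"echo times for {sid}/{label} do not match protocol")
        sigma = grp["noise_sigma"].iloc[0]
        out.setdefault(sid, {})[label] = EchoSeries(
            roi_means=grp["roi_mean"].to_numpy(),
            protocol=proto,
            noise_sigma=None if pd.isna(sigma) else float(sigma),
        )
    return out


# --- spectra I/O: per-record CSV + JSON sidecar ---------------------------


def write_mrs_series(series: SpectrumSeries, directory: str | Path) -> None:
    """Write one subject's spectra: ``te_XXXX.csv`` per record (t_s, real,
    imag) plus ``meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(series.n_points) / series.sweep_hz

    def _write(record: SpectrumRecord, name: str) -> None:
        pd.DataFrame(
            {"t_s": t, "real": record.fid.real, "imag": record.fid.imag}
        ).to_csv(directory / name, index=False)

    for record in series.records:
        _write(record, f"te_{int(round(record.te_ms)):04d}.csv")
    meta = {
        "sweep_hz": series.sweep_hz,
        "n_points": series.n_points,
        "tr_ms": series.tr_ms,
        "multi_te_ms": [r.te_ms for r in series.records],
        "n_averages_multi": series.records[0].n_averages if series.records else None,
        "single_echo_te_ms": None,
        "single_echo_tr_ms": series.single_echo_tr_ms,
        "n_averages_single": None,
    }
    if series.single_echo is not None:
        _write(series.single_echo, "single_echo.csv")
        meta["single_echo_te_ms"] = series.single_echo.te_ms
        meta["n_averages_single"] = series.single_echo.n_averages
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_mrs_series(directory: str | Path) -> SpectrumSeries:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())

    def _read(name: str, te_ms: float, n_averages: int) -> SpectrumRecord:
        frame = pd.read_csv(directory / name)
        fid = frame["real"].to_numpy() + 1j * frame["imag"].to_numpy()
        return SpectrumRecord(te_ms=te_ms, fid=fid, n_averages=n_averages)

    records = [
        _read(f"te_{int(round(te)):04d}.csv", te, meta["n_averages_multi"] or 1)
        for te in meta["multi_te_ms"]
    ]
    single = None
    if meta["single_echo_te_ms"] is not None:
        single = _read("single_echo.csv", meta["single_echo_te_ms"],
                       meta["n_averages_single"] or 1)
    return SpectrumSeries(
        records=records,
        sweep_hz=meta["sweep_hz"],
        n_points=meta["n_points"],
        tr_ms=meta["tr_ms"],
        single_echo=single,
        single_echo_tr_ms=meta.get("single_echo_tr_ms", 4000.0),
    )
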