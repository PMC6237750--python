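"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular formats are plain delimited text with unit-bearing headers:

* peak lists: ``residue,restype,methyl,dH_ppm,dC_ppm`` (csv dialect) or
  Sparky-style assignment lists (``I277CD1-HD1  12.345  0.678``: label,
  13C ppm, 1H ppm);
* progress curves / fluorescence traces: two columns (time_s, value);
* k_obs tables: ``dNTP_uM,kobs_per_s``;
* spectra: ``wavelength_nm,value``;
* dispersion data: ``residue,inv_taucp_per_s`` (or ``nu_cpmg_hz``),
  ``R2eff_per_s``, optional ``sigma_per_s``.

Residue numbers are 1-based sequence positions throughout.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cpmg as cpmg_mod
from . import fret as fret_mod
from . import kinetics as kin_mod
from . import shiftvec as sv_mod
from .cpmg import DispersionCurve
from .fret import Spectrum
from .kinetics import ProgressCurve
from .mechanism import FluorescenceTrace
from .shiftvec import (
    DEFAULT_SUBDOMAINS,
    MethylPeak,
    MethylPeakList,
    StateComparison,
    SubdomainMap,
)

__all__ = [
    "ParseError",
    "read_peak_list",
    "write_peak_list",
    "read_progress_curve",
    "write_progress_curve",
    "read_kobs_table",
    "write_kobs_table",
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "read_dispersion_table",
    "write_dispersion_table",
    "read_subdomain_map",
    "comparison_to_frame",
    "comparison_summary",
    "RunConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

_SPARKY_LABEL = re.compile(r"^([ILV])(\d+)([A-Z]{2}\d?)-[A-Z]+\d?$")


def _parse_sparky_label(label: str) -> tuple[str, int, str]:
    m = _SPARKY_LABEL.match(label)
    if m is None:
        raise ParseError(f"unparseable Sparky assignment label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def read_peak_list(path: str | Path, dialect: str = "csv", state_name: str | None = None) -> MethylPeakList:
    """Read a methyl peak list (``csv`` or ``sparky`` dialect)."""
    path = Path(path)
    name = state_name if state_name is not None else path.stem
    peaks: list[MethylPeak] = []
    if dialect == "csv":
        df = pd.read_csv(path)
        required = {"residue", "restype", "methyl", "dH_ppm", "dC_ppm"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in df.iterrows():
            try:
                peaks.append(
                    MethylPeak(
                        int(row["residue"]), str(row["restype"]).strip(),
                        str(row["methyl"]).strip(),
                        float(row["dH_ppm"]), float(row["dC_ppm"]),
                    )
                )
            except (ValueError, sv_mod.ShiftVecError) as exc:
                raise ParseError(f"{path} line {i + 2}: {exc}") from exc
    elif dialect == "sparky":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected 'label w1 w2'")
            try:
                rtype, res, methyl = _parse_sparky_label(fields[0])
                # Sparky C-H lists print w1 = 13C, w2 = 1H
                d_c, d_h = float(fields[1]), float(fields[2])
                peaks.append(MethylPeak(res, rtype, methyl, d_h, d_c))
            except (ValueError, ParseError, sv_mod.ShiftVecError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    else:
        raise ParseError(f"unknown peak-list dialect {dialect!r}")
    try:
        return MethylPeakList(state_name=name, peaks=peaks)
    except sv_mod.ShiftVecError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_peak_list(peaklist: MethylPeakList, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [p.residue_number for p in peaklist.peaks],
            "restype": [p.residue_type for p in peaklist.peaks],
            "methyl": [p.methyl_id for p in peaklist.peaks],
            "dH_ppm": [p.delta_H for p in peaklist.peaks],
            "dC_ppm": [p.delta_C for p in peaklist.peaks],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curves, traces, tables, spectra
# ---------------------------------------------------------------------------


def _read_two_column(path: str | Path, c0: str, c1: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in (c0, c1):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df[c0].to_numpy(float), df[c1].to_numpy(float)


def read_progress_curve(path: str | Path, label: str = "") -> ProgressCurve:
    t, y = _read_two_column(path, "time_s", "product_nM")
    return ProgressCurve(times=t, product=y, label=label or Path(path).stem)


def write_progress_curve(curve: ProgressCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": curve.times, "product_nM": curve.product}).to_csv(path, index=False)


def read_kobs_table(path: str | Path) -> list[tuple[float, float]]:
    c, k = _read_two_column(path, "dNTP_uM", "kobs_per_s")
    return list(zip(c.tolist(), k.tolist()))


def write_kobs_table(points, path: str | Path) -> None:
    pts = list(points)
    pd.DataFrame(
        {"dNTP_uM": [p[0] for p in pts], "kobs_per_s": [p[1] for p in pts]}
    ).to_csv(path, index=False)


def read_trace(path: str | Path, dNTP_concentration: float = 0.0, dead_time: float = 0.002) -> FluorescenceTrace:
    t, s = _read_two_column(path, "time_s", "signal")
    return FluorescenceTrace(
        times=t, signal=s, dNTP_concentration=dNTP_concentration,
        dead_time=dead_time, label=Path(path).stem,
    )


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "signal": trace.signal}).to_csv(path, index=False)


def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    w, v = _read_two_column(path, "wavelength_nm", "value")
    return Spectrum(w, v, kind)  # type: ignore[arg-type]


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "value": spectrum.values}
    ).to_csv(path, index=False)


def read_dispersion_table(path: str | Path) -> list[DispersionCurve]:
    """Read a long-format dispersion table into per-residue curves.

    Accepts either an ``inv_taucp_per_s`` column or ``nu_cpmg_hz``
    (converted via 1/tau_cp = 2 nu_CPMG); an optional ``sigma_per_s``
    column carries per-point uncertainties.
    """
    df = pd.read_csv(path)
    if "residue" not in df.columns or "R2eff_per_s" not in df.columns:
        raise ParseError(f"{path}: need 'residue' and 'R2eff_per_s' columns")
    if "inv_taucp_per_s" in df.columns:
        df = df.assign(_inv=df["inv_taucp_per_s"].astype(float))
    elif "nu_cpmg_hz" in df.columns:
        df = df.assign(_inv=2.0 * df["nu_cpmg_hz"].astype(float))
    else:
        raise ParseError(f"{path}: need 'inv_taucp_per_s' or 'nu_cpmg_hz'")
    curves = []
    for key, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("_inv")
        sigma = grp["sigma_per_s"].to_numpy(float) if "sigma_per_s" in grp.columns else None
        curves.append(
            DispersionCurve(
                residue_key=str(key),
                tau_cp_inverse=grp["_inv"].to_numpy(float),
                R2_eff=grp["R2eff_per_s"].to_numpy(float),
                uncertainties=sigma,
            )
        )
    return curves


def write_dispersion_table(curves, path: str | Path) -> None:
    frames = []
    for c in curves:
        frame = pd.DataFrame(
            {
                "residue": c.residue_key,
                "inv_taucp_per_s": c.tau_cp_inverse,
                "R2eff_per_s": c.R2_eff,
            }
        )
        if c.uncertainties is not None:
            frame["sigma_per_s"] = c.uncertainties
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_subdomain_map(path: str | Path) -> SubdomainMap:
    """YAML subdomain map: ``{lyase: [1, 87], thumb: [88, 151], ...}``."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping of name -> [lo, hi]")
    ranges = tuple((str(k), int(v[0]), int(v[1])) for k, v in raw.items())
    return SubdomainMap(ranges=ranges)


# ---------------------------------------------------------------------------
# comparison output
# ---------------------------------------------------------------------------


def comparison_to_frame(comparison: StateComparison) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [r.peak_key[0] for r in comparison.rows],
            "methyl": [r.peak_key[1] for r in comparison.rows],
            "restype": [r.residue_type for r in comparison.rows],
            "subdomain": [r.subdomain for r in comparison.rows],
            "combined_shift_ppm": [r.combined_shift for r in comparison.rows],
            "delta_n": [r.delta_n for r in comparison.rows],
            "cos_theta": [r.cos_theta for r in comparison.rows],
            "classification": [r.classification for r in comparison.rows],
        }
    )


def comparison_summary(comparison: StateComparison) -> dict:
    return {
        "test_state": comparison.test_state,
        "reference_open": comparison.reference_open,
        "reference_closed": comparison.reference_closed,
        "counts": comparison.counts,
        "rmsd_global": comparison.rmsd_global,
        "rmsd_by_subdomain": comparison.rmsd_by_subdomain,
        "mean_delta_n": comparison.mean_delta_n,
        "mean_cos_theta": comparison.mean_cos_theta,
        "n_unmatched": len(comparison.unmatched_keys),
    }


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths and thresholds for an end-to-end analysis run.

    Any stage whose inputs are absent is skipped (and noted in the log);
    a stage that fails is recorded and the remaining stages still run.
    """

    out_dir: str
    seed: int = 0
    # shiftvec
    test_peaks: str | None = None
    open_peaks: str | None = None
    closed_peaks: str | None = None
    subdomain_map: str | None = None
    significance_ppm: float = 0.025
    cos_cutoff: float = 0.8
    # kinetics
    burst_curve: str | None = None
    kobs_table: str | None = None
    # fret
    donor_spectrum: str | None = None
    acceptor_spectrum: str | None = None
    fda: float | None = None
    fd: float | None = None
    # cpmg
    dispersion_table: str | None = None
    alpha: float = 0.05
    rex_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.significance_ppm < 0 or self.rex_cutoff < 0:
            raise ValueError("thresholds must be >= 0")
        if not (-1.0 < self.cos_cutoff < 1.0):
            raise ValueError("cos_cutoff must lie in (-1, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; write tables, a JSON summary and a log.

    Returns the summary dict.  The summary records the schema version, the
    seed, a hash of the configuration, per-stage results and per-stage
    errors; the process-level exit policy (nonzero on any stage failure)
    belongs to the CLI wrapper.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "errors": {},
        "skipped": [],
    }
    log_lines = [f"seed={config.seed}", f"config_hash={summary['config_hash']}"]
    try:
        import numpy, scipy  # noqa: PLC0415

        log_lines.append(f"numpy={numpy.__version__} scipy={scipy.__version__}")
    except Exception:
        pass

    # --- shiftvec ---
    if config.test_peaks and config.open_peaks and config.closed_peaks:
        try:
            subdomains = (
                read_subdomain_map(config.subdomain_map)
                if config.subdomain_map
                else DEFAULT_SUBDOMAINS
            )
            comp = sv_mod.compare_states(
                read_peak_list(config.test_peaks),
                read_peak_list(config.open_peaks),
                read_peak_list(config.closed_peaks),
                subdomains,
                threshold=config.significance_ppm,
                cos_cutoff=config.cos_cutoff,
            )
            comparison_to_frame(comp).to_csv(out / "shiftvec_rows.csv", index=False)
            summary["stages"]["shiftvec"] = comparison_summary(comp)
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            summary["errors"]["shiftvec"] = str(exc)
    else:
        summary["skipped"].append("shiftvec")

    # --- kinetics ---
    if config.burst_curve or config.kobs_table:
        try:
            stage: dict = {}
            if config.burst_curve:
                fit = kin_mod.fit_burst(read_progress_curve(config.burst_curve))
                stage["burst"] = {
                    "E_app_nM": fit.E_app, "k_obs_per_s": fit.k_obs,
                    "k_ss_per_s": fit.k_ss, "residual_norm": fit.residual_norm,
                }
            if config.kobs_table:
                sat = kin_mod.fit_saturation(read_kobs_table(config.kobs_table))
                stage["saturation"] = {
                    "k_pol_per_s": sat.k_pol, "K_d_dNTP_uM": sat.K_d_dNTP,
                    "ill_conditioned": sat.ill_conditioned,
                }
            summary["stages"]["kinetics"] = stage
        except Exception as exc:  # noqa: BLE001
            summary["errors"]["kinetics"] = str(exc)
    else:
        summary["skipped"].append("kinetics")

    # --- fret ---
    if config.donor_spectrum and config.acceptor_spectrum:
        try:
            donor = read_spectrum(config.donor_spectrum, "emission")
            acceptor = read_spectrum(config.acceptor_spectrum, "extinction")
            J = fret_mod.overlap_integral(donor, acceptor)
            params = fret_mod.FretParameters(J=J)
            R0 = fret_mod.forster_radius(params)
            stage = {"J_M1cm3": J, "R0_A": R0}
            if config.fda is not None and config.fd is not None:
                E = fret_mod.efret(config.fda, config.fd)
                stage["efficiency"] = E
                if 0.0 < E < 1.0:
                    stage["distance_A"] = fret_mod.distance_from_efficiency(E, R0)
            summary["stages"]["fret"] = stage
        except Exception as exc:  # noqa: BLE001
            summary["errors"]["fret"] = str(exc)
    else:
        summary["skipped"].append("fret")

    # --- cpmg ---
    if config.dispersion_table:
        try:
            curves = read_dispersion_table(config.dispersion_table)
            fits = [
                cpmg_mod.fit_dispersion(
                    c, alpha=config.alpha, rex_cutoff=config.rex_cutoff
                )
                for c in curves
            ]
            pd.DataFrame(
                {
                    "residue": [f.residue_key for f in fits],
                    "R2_0_per_s": [f.R2_0 for f in fits],
                    "Rex_per_s": [f.R_ex for f in fits],
                    "kex_per_s": [f.k_ex for f in fits],
                    "model": [f.model_choice for f in fits],
                    "flexible": [f.flexible for f in fits],
                }
            ).to_csv(out / "cpmg_fits.csv", index=False)
            summary["stages"]["cpmg"] = {
                "n_residues": len(fits),
                "n_flexible": cpmg_mod.count_flexible(fits),
            }
        except Exception as exc:  # noqa: BLE001
            summary["errors"]["cpmg"] = str(exc)
    else:
        summary["skipped"].append("cpmg")

    for name in summary["stages"]:
        log_lines.append(f"stage {name}: ok")
    for name, err in summary["errors"].items():
        log_lines.append(f"stage {name}: FAILED ({err})")
    for name in summary["skipped"]:
        log_lines.append(f"stage {name}: skipped (inputs not configured)")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
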