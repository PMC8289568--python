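"""Pipeline orchestration and report tables for the tiered assessment.

``run_pipeline`` executes the whole tier sequence — guideline screening,
descriptive statistics and correlations, dual-family exposure fits with KS
diagnostics, SSD hazardous concentrations with bootstrap lower limits, the
exposure x effects convolution, and remediation targets — and writes the
result tables as CSV plus a machine-readable JSON run log.  Outputs are a
pure function of the :class:`RunConfig` (seed included): same config, same
bytes.

The hazard and target tables are reported in ng/g (the customary unit for
SSD-derived quantities) while survey-side tables stay in mg/kg; zero
required reduction renders as "NIL".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    ExposureTable,
    GuidelineSet,
    ToxicityDataset,
    read_exposure_table,
    read_guidelines,
    read_toxicity,
    write_toxicity,
)
from .distributions import fit_pdd
from .hazard import hc_table
from .risk import (
    RemediationResult,
    RiskResult,
    required_reduction_for_risk,
    species_affected,
)
from .screening import percentile_guard, screen
from .summary import element_summary, pearson_matrix
from .synthetic import gen_toxicity, wami_like_scenario
from .units import convert_units

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_table6",
           "render_correlations"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one serialisable record."""

    exposure_path: str
    guidelines_path: str
    toxicity_paths: dict = field(default_factory=dict)  # element -> CSV path
    elements: tuple | None = None          # None = all elements in the table
    seed: int = 0
    protection_levels: tuple = (5.0, 10.0, 25.0)
    confidence_levels: tuple = (50.0, 95.0)
    n_boot_hc: int = 2000
    n_boot_risk: int = 200
    n_boot_ks: int = 199
    ssd_family: str = "burr3"
    pdd_family: str = "auto"
    hc_unit: str = "ng/g"
    exposure_unit: str = "mg/kg"
    reduction_dp: int = 1
    synthetic_toxicity: bool = True        # emulate effect data when no CSVs given

    def __post_init__(self) -> None:
        for n in self.protection_levels:
            if not (0 < n < 100):
                raise ValueError(f"protection level {n} outside (0, 100)")
        for c in self.confidence_levels:
            if not (50 <= c <= 99.9):
                raise ValueError(f"confidence level {c} outside [50, 99.9]")
        if self.seed is None:
            raise ValueError("seed is required: every stochastic stage consumes it")


@dataclass
class ReportBundle:
    summary: pd.DataFrame
    correlations: pd.DataFrame
    screening: pd.DataFrame
    fits: dict
    hc: pd.DataFrame
    table6: pd.DataFrame
    log: dict
    written: list = field(default_factory=list)


def _element_seed(base: int, idx: int, stage: int) -> int:
    # deterministic per-element, per-stage substreams; stays below 2^31
    return (int(base) * 1009 + idx * 101 + stage * 13) % (2**31 - 1)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Execute screen -> fit -> (ssd, hc) -> risk -> remediate and render tables."""
    exposure = read_exposure_table(config.exposure_path, unit=config.exposure_unit)
    guidelines = read_guidelines(config.guidelines_path)
    elements = list(config.elements) if config.elements else exposure.elements
    warnings_log = list(guidelines.warnings)

    summary = element_summary(exposure)
    corr = pearson_matrix(exposure)
    screening = screen(exposure, guidelines)

    fits: dict[str, dict] = {}
    risk_results: dict[str, RiskResult] = {}
    remediation: dict[tuple[str, float], RemediationResult] = {}
    hc_frames = []
    report_conf = max(config.confidence_levels)

    for idx, el in enumerate(elements):
        x = exposure.column(el)
        pdd = fit_pdd(x, unit=exposure.unit, n_boot=config.n_boot_ks,
                      seed=_element_seed(config.seed, idx, 1))
        sel = getattr(pdd, pdd.selected)
        guard = None
        if el in guidelines.elements:
            low = guidelines.to_unit(exposure.unit).low(el)
            ok, p99 = percentile_guard(sel, 0.99, low)
            guard = {"q99": p99, "low_trigger": low, "passes": ok}
        fits[el] = {
            "selected": pdd.selected,
            "lognormal": {"mu": pdd.lognormal.params.mu,
                          "sigma": pdd.lognormal.params.sigma,
                          "ks_d": pdd.lognormal.ks_d, "ks_p": pdd.lognormal.ks_p},
            "burr3": {"b": pdd.burr3.params.b, "c": pdd.burr3.params.c,
                      "k": pdd.burr3.params.k,
                      "ks_d": pdd.burr3.ks_d, "ks_p": pdd.burr3.ks_p},
            "percentile_guard": guard,
        }

        tox = _toxicity_for(config, el, idx)
        if tox is None:
            continue

        ht = hc_table(
            tox,
            n_percents=config.protection_levels,
            confidences=config.confidence_levels,
            n_boot=config.n_boot_hc,
            seed=_element_seed(config.seed, idx, 2),
            family=config.ssd_family,
        )
        if ht.attrs["n_failed"]:
            warnings_log.append(
                f"{el}: {ht.attrs['n_failed']} HC bootstrap refits dropped"
            )
        ht_out = convert_units(ht, exposure.unit, config.hc_unit)
        ht_out.insert(0, "element", el)
        hc_frames.append(ht_out)

        risk_results[el] = species_affected(
            x, tox,
            confidence_percent=report_conf,
            n_boot=config.n_boot_risk,
            seed=_element_seed(config.seed, idx, 3),
            pdd_family=config.pdd_family,
            ssd_family=config.ssd_family,
        )
        for n in config.protection_levels:
            remediation[(el, n)] = required_reduction_for_risk(
                x, tox, n,
                confidence_percent=report_conf,
                n_boot=config.n_boot_risk,
                seed=_element_seed(config.seed, idx, 3),  # shared replicate stream
                pdd_family=config.pdd_family,
                ssd_family=config.ssd_family,
            )

    hc = pd.concat(hc_frames) if hc_frames else pd.DataFrame()
    table6 = render_table6(risk_results, remediation, config.protection_levels,
                           hc_unit=config.hc_unit, source_unit=exposure.unit,
                           dp=config.reduction_dp)
    log = {
        "sedrisk_version": __version__,
        "seed": config.seed,
        "elements": elements,
        "n_boot": {"hc": config.n_boot_hc, "risk": config.n_boot_risk,
                   "ks": config.n_boot_ks},
        "confidence_levels": list(config.confidence_levels),
        "protection_levels": list(config.protection_levels),
        "ssd_family": config.ssd_family,
        "synthetic_toxicity": bool(
            config.synthetic_toxicity and not config.toxicity_paths
        ),
        "toxicity_label": (
            "emulation (synthetic SSD scenarios; not measured effect data)"
            if config.synthetic_toxicity and not config.toxicity_paths else "user-supplied"
        ),
        "warnings": warnings_log,
        "risk": {
            el: {"percent_affected": r.percent_affected,
                 "point_percent": r.point_percent,
                 "confidence": r.confidence_percent,
                 "n_failed": r.n_failed}
            for el, r in risk_results.items()
        },
    }
    bundle = ReportBundle(
        summary=summary.table, correlations=render_correlations(corr),
        screening=screening.to_frame(), fits=fits, hc=hc, table6=table6, log=log,
    )
    if outdir is not None:
        bundle.written = _write_bundle(bundle, Path(outdir))
    return bundle


def _toxicity_for(config: RunConfig, element: str, idx: int) -> ToxicityDataset | None:
    if element in config.toxicity_paths:
        return read_toxicity(config.toxicity_paths[element], element)
    if not config.synthetic_toxicity:
        return None
    try:
        spec = wami_like_scenario(element, _element_seed(config.seed, idx, 4))
    except ValueError:
        return None
    return gen_toxicity(spec)


def _fmt(x: float, dp: int) -> str:
    return f"{x:.{dp}f}"


def render_table6(
    risk: dict[str, RiskResult],
    remediation: dict[tuple[str, float], RemediationResult],
    protection_levels,
    hc_unit: str = "ng/g",
    source_unit: str = "mg/kg",
    dp: int = 1,
) -> pd.DataFrame:
    """The remediation summary: % affected, required reduction, median target.

    One row per element; for each protection level n a ``HC{n}`` column in
    each of the three blocks.  The % affected block repeats the same number
    across protection levels by construction (it depends only on the current
    exposure).  Zero reduction renders as "NIL"; targets are converted to
    ``hc_unit`` at ``dp`` decimals.
    """
    rows = {}
    for el, r in risk.items():
        row = {}
        for n in protection_levels:
            if (el, n) not in remediation:
                raise KeyError(f"missing remediation result for ({el}, HC{n:g})")
        for n in protection_levels:
            row[f"affected_HC{n:g}"] = _fmt(r.percent_affected, dp)
        for n in protection_levels:
            red = remediation[(el, n)].required_reduction_percent
            row[f"reduction_HC{n:g}"] = "NIL" if red == 0.0 else _fmt(red, dp)
        for n in protection_levels:
            tgt = convert_units(remediation[(el, n)].median_target, source_unit, hc_unit)
            row[f"target_HC{n:g}"] = _fmt(tgt, dp)
        rows[el] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "element"
    return out


def render_correlations(corr, dp: int = 2) -> pd.DataFrame:
    """Lower-triangle correlation table with significance asterisks."""
    els = list(corr.r.index)
    out = pd.DataFrame("", index=els, columns=els)
    for i, a in enumerate(els):
        for j, b in enumerate(els[: i + 1]):
            cell = f"{corr.r.loc[a, b]:.{dp}f}"
            if i != j and bool(corr.significant.loc[a, b]):
                cell += "*"
            out.loc[a, b] = cell
    out.index.name = "element"
    return out


def _write_bundle(bundle: ReportBundle, outdir: Path) -> list:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p)
        written.append(str(p))

    _csv(bundle.summary, "summary.csv")
    _csv(bundle.correlations, "correlations.csv")
    _csv(bundle.screening, "screening.csv")
    if not bundle.hc.empty:
        _csv(bundle.hc, "hc.csv")
    _csv(bundle.table6, "remediation.csv")
    for name, payload in (("fits.json", bundle.fits), ("run_log.json", bundle.log)):
        p = outdir / name
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(str(p))
    return written
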