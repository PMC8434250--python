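"""End-to-end runs: config, orchestration, and report serialization.

A run processes each sample through the standard chain — average
replicates, crop, baseline-correct, normalize to the 1460 cm^-1 reference
band — then decomposes each configured region and quantifies it against
its assignment scheme.  Reports are written as JSON (full detail) and a
flat per-sample feature-matrix CSV suitable for external ordination or
heat-map tools.  Every JSON report embeds the config hash and library
version so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .banddecomp import decompose_region
from .io import Spectrum, read_spectrum, write_spectrum
from .preprocess import average_replicates, baseline_correct, crop, normalize_to_band
from .quantify import (
    AMIDE_I_PROTOCOL,
    AMIDE_I_SCHEME,
    SS_PROTOCOL,
    SS_CONFORMER_SCHEME,
    AssignmentScheme,
    detect_marker_bands,
    feature_vector,
    quantify_amide_i,
    quantify_ss_conformers,
    tryptophan_intensity,
    tyrosine_doublet_ratio,
)

__all__ = ["RunConfig", "RegionConfig", "run_pipeline", "load_config"]

log = logging.getLogger("ramandecomp")

SCHEMES: dict[str, AssignmentScheme] = {
    "amide_i": AMIDE_I_SCHEME,
    "ss_conformers": SS_CONFORMER_SCHEME,
}

#: composite-correlation levels below which a fit is logged as suspect
QUALITY_THRESHOLDS = {"ss_conformers": 0.9985, "amide_i": 0.9991}


REGION_PROTOCOLS = {"amide_i": AMIDE_I_PROTOCOL, "ss_conformers": SS_PROTOCOL}

#: quiet zones of a kernel-endosperm spectrum (between the marker bands)
#: whose minima anchor the polynomial fluorescence-background fit
ENDOSPERM_BASELINE_ANCHORS = [
    (300.0, 330.0), (560.0, 610.0), (742.0, 752.0), (780.0, 800.0),
    (895.0, 912.0), (975.0, 1015.0), (1160.0, 1220.0), (1410.0, 1435.0),
    (1520.0, 1560.0), (1700.0, 2000.0),
]


@dataclass
class RegionConfig:
    """Per-region fit block; unset knobs fall back to the scheme protocol."""

    name: str
    region: tuple[float, float]
    scheme: str | None = None
    shape_policy: str | None = None
    seed_fwhm: float | None = None
    min_prominence: float | None = None
    smooth_window: int | None = None
    target_r: float | None = None
    max_extra: int = 3

    def resolved(self) -> dict:
        proto = REGION_PROTOCOLS.get(self.scheme or "", {})
        return {
            "shape_policy": self.shape_policy or proto.get("shape_policy", "pseudo_voigt"),
            "seed_fwhm": (self.seed_fwhm if self.seed_fwhm is not None
                          else proto.get("seed_fwhm", 12.0)),
            "min_prominence": (self.min_prominence if self.min_prominence is not None
                               else proto.get("min_prominence", 0.02)),
        }


@dataclass
class RunConfig:
    samples: list[dict]                    # [{"id": ..., "replicates": [paths or globs]}]
    output_dir: str = "ramandecomp_out"
    dialect: str = "csv"
    seed: int = 0
    crop_region: tuple[float, float] | None = (300.0, 2000.0)
    baseline_kind: str = "linear"
    baseline_anchors: list[tuple[float, float]] | None = None
    baseline_degree: int = 4
    normalize: bool = True
    ref_center: float = 1460.0
    ref_window: tuple[float, float] = (1450.0, 1470.0)
    grid_step: float | None = None
    regions: list[RegionConfig] = field(default_factory=list)
    markers: bool = False
    verbosity: str = "warning"

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.scheme is not None and r.scheme not in SCHEMES:
                raise ValueError(f"unknown scheme {r.scheme!r} in region {r.name!r}")
            if self.crop_region is not None:
                lo, hi = self.crop_region
                if not (lo <= r.region[0] and r.region[1] <= hi):
                    raise ValueError(f"region {r.name!r} outside crop range")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    """Load a YAML run config; nested region blocks become RegionConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    regions = [RegionConfig(**{**r, "region": tuple(r["region"])}) for r in raw.pop("regions", [])]
    for key in ("crop_region", "ref_window"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    if raw.get("baseline_anchors") is not None:
        raw["baseline_anchors"] = [tuple(a) for a in raw["baseline_anchors"]]
    return RunConfig(regions=regions, **raw)


def _expand(paths: list[str]) -> list[str]:
    out: list[str] = []
    for p in paths:
        hits = sorted(globmod.glob(p))
        out.extend(hits if hits else [p])
    return out


def _preprocess_sample(spectra: list[Spectrum], cfg: RunConfig) -> tuple[Spectrum, np.ndarray]:
    mean, sd = average_replicates(spectra, cfg.grid_step)
    if cfg.crop_region is not None:
        mean = crop(mean, cfg.crop_region)
    mean, _ = baseline_correct(mean, cfg.baseline_kind, cfg.baseline_anchors, cfg.baseline_degree)
    if cfg.normalize:
        mean, _ = normalize_to_band(mean, cfg.ref_center, cfg.ref_window)
    return mean, sd


def _quantify_region(result, rc: RegionConfig) -> dict[str, Any]:
    block: dict[str, Any] = {
        "region": list(rc.region),
        "pearson_r": result.pearson_r,
        "residual_rms": result.residual_rms,
        "converged": result.converged,
        "components": result.to_table(),
    }
    threshold = QUALITY_THRESHOLDS.get(rc.scheme or "", None)
    if threshold is not None and result.pearson_r < threshold:
        log.warning("region %s: pearson r %.5f below quality level %.4f",
                    rc.name, result.pearson_r, threshold)
    if rc.scheme == "amide_i":
        rep = quantify_amide_i(result, SCHEMES[rc.scheme])
        block["fractions"] = rep.fractions
        block["aromatic_areas"] = rep.aromatic_areas
        block["unassigned"] = [c.center for c in rep.unassigned]
        block["_report"] = rep
    elif rc.scheme == "ss_conformers":
        rep = quantify_ss_conformers(result, SCHEMES[rc.scheme])
        block["fractions"] = rep.fractions
        block["member_bands"] = rep.member_bands
        block["_report"] = rep
    return block


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured run; returns a summary with report paths."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.WARNING))
    os.makedirs(config.output_dir, exist_ok=True)
    summary: dict[str, Any] = {
        "config_hash": config.hash(),
        "version": __version__,
        "samples": [],
        "warnings": [],
        "reports": [],
    }
    feature_rows = []
    for sample in config.samples:
        sid = sample["id"]
        paths = _expand(sample["replicates"])
        if not paths or not all(os.path.exists(p) for p in paths):
            raise FileNotFoundError(f"sample {sid!r}: missing replicate file(s) in {paths}")
        spectra = [read_spectrum(p, config.dialect) for p in paths]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            processed, sd = _preprocess_sample(spectra, config)
            report: dict[str, Any] = {
                "sample_id": sid,
                "n_replicates": len(spectra),
                "config_hash": config.hash(),
                "version": __version__,
                "regions": {},
            }
            structure = conformers = markers_rep = None
            for rc in config.regions:
                result = decompose_region(
                    processed, rc.region,
                    smooth_window=rc.smooth_window,
                    scheme=SCHEMES.get(rc.scheme) if rc.scheme else None,
                    target_r=rc.target_r,
                    max_extra=rc.max_extra,
                    **rc.resolved(),
                )
                block = _quantify_region(result, rc)
                rep = block.pop("_report", None)
                if rc.scheme == "amide_i":
                    structure = rep
                elif rc.scheme == "ss_conformers":
                    conformers = rep
                report["regions"][rc.name] = block
            if config.markers:
                table = detect_marker_bands(processed)
                report["markers"] = table
                from .quantify import MarkerReport

                markers_rep = MarkerReport()
                try:
                    markers_rep = tyrosine_doublet_ratio(processed)
                except ValueError:
                    pass
                try:
                    markers_rep.trp_intensity = tryptophan_intensity(processed)
                except ValueError:
                    pass
                report["tyr_ratio"] = markers_rep.tyr_ratio
                report["tyr_category"] = markers_rep.tyr_category
                report["trp_760"] = markers_rep.trp_intensity
        for w in caught:
            summary["warnings"].append(f"{sid}: {w.message}")
        row = {"sample_id": sid}
        row.update(feature_vector(structure, conformers, markers_rep))
        feature_rows.append(row)
        out_json = os.path.join(config.output_dir, f"{sid}_report.json")
        with open(out_json, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        proc_path = os.path.join(config.output_dir, f"{sid}_processed.csv")
        write_spectrum(processed, proc_path)
        summary["samples"].append(sid)
        summary["reports"].append(out_json)
    matrix_path = os.path.join(config.output_dir, "feature_matrix.csv")
    pd.DataFrame(feature_rows).to_csv(matrix_path, index=False)
    summary["feature_matrix"] = matrix_path
    return summary
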