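"""Configuration-driven end-to-end analysis pipeline.

Stages: simulate (phantoms per participant x timepoint, or a cohort
table) -> voxel-wise T2 fitting on the load-bearing slices -> laminar
splitting -> region x layer means and the composite -> thickness on a
finer grid -> group x time mixed models -> contrast CSV, JSON model
report and a manifest with content hashes.  Reruns with the same config
and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort import CohortSpec, generate_cohort
from .geometry import (
    regional_thickness,
    resample_mask,
    select_loadbearing_slices,
    split_all_regions,
)
from .images import BACKGROUND, CartilageMask
from .phantom import PhantomSpec, generate_phantom
from .relaxometry import FitOptions, fit_map
from .stats import COMPOSITE_REGION, GroupTimeModel, composite, region_layer_means

log = logging.getLogger("cartiq.pipeline")

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "source",
    "groups",
    "phantom",
    "cohort",
    "fit",
    "central_slice",
    "t2_slices",
    "thickness_slices",
    "thickness_upsample",
    "sidak_m",
    "covariates",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled in.

    ``source`` selects the simulation arm: ``"phantom"`` images a small
    cohort of synthetic knees per group and timepoint; ``"cohort"`` draws
    the measurement table directly from the statistical generative model.
    T2 mapping uses 3 slices around the central landmark slice and
    thickness uses 7, mirroring the difference in slice coverage between
    the mapping and morphometry acquisitions.
    """

    seed: int
    output_dir: str = "cartiq-out"
    source: str = "phantom"
    groups: dict[str, int] = field(default_factory=lambda: {"healthy": 2, "at-risk": 2})
    phantom: dict[str, Any] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)
    central_slice: int = 4
    t2_slices: int = 3
    thickness_slices: int = 7
    thickness_upsample: int = 2
    sidak_m: int | None = None
    covariates: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML or TOML pipeline config.

    All violations are collected and reported together.  Defaults are
    filled in and echoed to the log.
    """
    path = Path(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config_dict(raw, origin=str(path))


def validate_config_dict(raw: dict[str, Any], origin: str = "<dict>") -> PipelineConfig:
    errors = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    if raw.get("source", "phantom") not in ("phantom", "cohort"):
        errors.append("source must be 'phantom' or 'cohort'")
    if "seed" not in raw or not isinstance(raw["seed"], int):
        errors.append("an integer seed is required whenever a generator is used")
    for key, default in (("t2_slices", 3), ("thickness_slices", 7)):
        n = raw.get(key, default)
        if not isinstance(n, int) or n < 1 or n % 2 == 0:
            errors.append(f"{key} must be a positive odd integer, got {n!r}")
    groups = raw.get("groups", {"healthy": 2, "at-risk": 2})
    if not isinstance(groups, dict) or len(groups) < 2 or any(
        not isinstance(v, int) or v < 1 for v in groups.values()
    ):
        errors.append("groups must map >=2 group labels to positive sizes")
    if errors:
        raise ValueError(f"invalid config {origin}: " + "; ".join(errors))

    cfg = PipelineConfig(
        seed=raw["seed"],
        output_dir=raw.get("output_dir", "cartiq-out"),
        source=raw.get("source", "phantom"),
        groups=dict(groups),
        phantom=dict(raw.get("phantom", {})),
        cohort=dict(raw.get("cohort", {})),
        fit=dict(raw.get("fit", {})),
        central_slice=raw.get("central_slice", 4),
        t2_slices=raw.get("t2_slices", 3),
        thickness_slices=raw.get("thickness_slices", 7),
        thickness_upsample=raw.get("thickness_upsample", 2),
        sidak_m=raw.get("sidak_m"),
        covariates=list(raw.get("covariates", [])),
        log_level=raw.get("log_level", "INFO"),
    )
    log.info("validated config %s: %s", origin, cfg.to_dict())
    return cfg


# ---------------------------------------------------------------------------
# simulation arms
# ---------------------------------------------------------------------------

def _per_cell(value: Any, group: str, default: float) -> float:
    if isinstance(value, dict):
        return float(value.get(group, default))
    if value is None:
        return default
    return float(value)


def _phantom_spec_for(cfg: PipelineConfig, group: str, time: str) -> PhantomSpec:
    p = cfg.phantom
    base = PhantomSpec()
    t2s = _per_cell(p.get("t2_superficial"), group, base.t2_superficial)
    t2d = _per_cell(p.get("t2_deep"), group, base.t2_deep)
    if time == "post":
        t2s += _per_cell(p.get("post_shift_superficial", -3.8), group, -3.8)
        t2d += _per_cell(p.get("post_shift_deep", 0.0), group, 0.0)
    kwargs: dict[str, Any] = {}
    for key in (
        "shape",
        "pixel_size",
        "slice_thickness",
        "bone_center",
        "bone_radius",
        "shell_thickness",
        "region_ids",
        "pd",
        "echo_times",
        "alpha",
        "sigma",
        "geometry",
        "arc",
    ):
        if key in p:
            v = p[key]
            kwargs[key] = tuple(v) if isinstance(v, list) else v
    return dataclasses.replace(base, t2_superficial=t2s, t2_deep=t2d, **kwargs)


def _child_seed(seed: int, *idx: int) -> int:
    """Deterministic sub-seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, *idx]).generate_state(1)[0] & 0x7FFFFFFF)


def _restrict_slices(mask: CartilageMask, slices: range) -> CartilageMask:
    labels = np.full_like(mask.labels, BACKGROUND)
    labels[list(slices)] = mask.labels[list(slices)]
    return CartilageMask(labels, mask.grid, dict(mask.region_names))


def _imaging_arm(cfg: PipelineConfig, out: Path) -> tuple[pd.DataFrame, list[Path]]:
    """Simulate, fit and measure one synthetic knee per participant x time."""
    fit_opts = FitOptions(**cfg.fit)
    rows = []
    artifacts: list[Path] = []
    maps_dir = out / "maps"
    participant_index = 0
    for group, n in cfg.groups.items():
        for i in range(n):
            pid = f"{group}-{i + 1:02d}"
            for t_idx, time in enumerate(("pre", "post")):
                spec = _phantom_spec_for(cfg, group, time)
                seed = _child_seed(cfg.seed, participant_index, t_idx)
                series, mask, truth = generate_phantom(spec, seed)
                n_total = mask.labels.shape[0]
                t2_range = select_loadbearing_slices(
                    n_total, cfg.central_slice, cfg.t2_slices
                )
                th_range = select_loadbearing_slices(
                    n_total, cfg.central_slice, cfg.thickness_slices
                )

                t2_mask = _restrict_slices(mask, t2_range)
                t2map = fit_map(series, t2_mask, fit_opts)
                laminae = split_all_regions(t2_mask)
                means = region_layer_means(
                    t2map, laminae, t2_range, mask.region_names
                )
                means.insert(0, "participant_id", pid)
                means.insert(1, "group", group)
                means.insert(2, "time", time)
                rows.append(means)

                # thickness on the finer morphometry grid
                fine = mask.grid.with_pixel_size(
                    mask.grid.pixel_size / cfg.thickness_upsample
                )
                fine_shape = (
                    mask.labels.shape[0],
                    mask.labels.shape[1] * cfg.thickness_upsample,
                    mask.labels.shape[2] * cfg.thickness_upsample,
                )
                fine_mask = resample_mask(mask, fine, fine_shape)
                for region in fine_mask.regions:
                    summ = regional_thickness(fine_mask, region, th_range)
                    rows.append(
                        pd.DataFrame(
                            [
                                {
                                    "participant_id": pid,
                                    "group": group,
                                    "time": time,
                                    "region": mask.region_names.get(
                                        region, str(region)
                                    ),
                                    "layer": "full",
                                    "value": summ.mean_thickness,
                                    "n_voxels": summ.n_voxels,
                                }
                            ]
                        )
                    )

                artifacts += cio.save_t2_map(t2map, maps_dir, f"{pid}_{time}")
                artifacts.append(
                    cio.save_laminar_mask(laminae, maps_dir / f"{pid}_{time}_laminae.nii")
                )
                if participant_index == 0 and t_idx == 0:
                    artifacts += cio.save_echo_series(series, out / "example_echoes.nii")
                    artifacts += cio.save_mask(mask, out / "example_mask.nii")
                log.info("imaged %s %s (seed %d)", pid, time, seed)
            participant_index += 1
    table = pd.concat(rows, ignore_index=True)
    table["age"] = np.nan
    table["bmi"] = np.nan
    return table, artifacts


def _cohort_arm(cfg: PipelineConfig) -> pd.DataFrame:
    kwargs = dict(cfg.cohort)
    if "cell_means" in kwargs:
        kwargs["cell_means"] = {
            tuple(k.split("|")): v for k, v in kwargs["cell_means"].items()
        }
    if "group_sizes" not in kwargs:
        kwargs["group_sizes"] = cfg.groups
    spec = CohortSpec(**kwargs)
    return generate_cohort(spec, _child_seed(cfg.seed, 0))


# ---------------------------------------------------------------------------
# analysis + reporting
# ---------------------------------------------------------------------------

def analyze_table(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    m_sidak: int | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Fit the group x time model for every region x layer cell present,
    plus the superficial and deep composites when all regions are there.

    Returns the tidy contrast table and a JSON-ready model report.
    """
    work = table.copy()
    for layer in ("superficial", "deep"):
        if (work["layer"] == layer).any() and not (
            (work["region"] == COMPOSITE_REGION) & (work["layer"] == layer)
        ).any():
            comp = composite(work, layer=layer)
            work = pd.concat([work, comp], ignore_index=True)

    all_rows = []
    report: dict[str, Any] = {"models": {}}
    cells = work[["region", "layer"]].drop_duplicates().itertuples(index=False)
    for region, layer in cells:
        try:
            res = GroupTimeModel(
                work, region, layer, covariates=tuple(covariates)
            ).fit(m_sidak=m_sidak)
        except ValueError as exc:
            log.warning("skipping cell (%s, %s): %s", region, layer, exc)
            continue
        tab = res.contrasts.copy()
        tab.insert(0, "region", region)
        tab.insert(1, "layer", layer)
        tab["m"] = res.m_sidak
        all_rows.append(tab)
        report["models"][f"{region}/{layer}"] = {
            "sigma_b2": res.sigma_b2,
            "sigma_e2": res.sigma_e2,
            "converged": res.converged,
            "degenerate": res.degenerate,
            "n_obs": res.n_obs,
            "n_participants": res.n_participants,
            "groups": res.groups,
            "cell_means": res.cell_means.to_dict(orient="records"),
        }
    if not all_rows:
        raise RuntimeError("no response cell could be modelled")
    return pd.concat(all_rows, ignore_index=True), report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and write the report bundle.

    Returns the manifest: config, seed, per-file content hashes and the
    headline contrasts.  Stage failures abort with a stage-tagged error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    try:
        if config.source == "phantom":
            table, artifacts = _imaging_arm(config, out)
        else:
            table = _cohort_arm(config)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        artifacts.append(cio.save_table(table, out / "measurements.csv"))
    except Exception as exc:
        raise RuntimeError(f"[measurements] {exc}") from exc

    try:
        contrast_tab, report = analyze_table(
            table, tuple(config.covariates), config.sidak_m
        )
        artifacts.append(cio.save_table(contrast_tab, out / "contrasts.csv"))
        report_path = out / "model_report.json"
        report_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
        artifacts.append(report_path)
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("pipeline complete: %d outputs in %s", len(artifacts), out)
    return manifest
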