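"""End-to-end orchestration: generate -> segment -> measure -> scale.

A run is driven by a YAML config, writes per-specimen artifacts plus
series-level fits into an output directory, and records a manifest
(config, seed, package version, input hashes) for reproducible re-runs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .allometry import carapace_dimensions, summarize_series
from .morpho import (carapace_surface_area, compute_scute_stats,
                     normalize_stats)
from .segment import build_rag, extract_surface, propagate_contours, \
    threshold_segment
from .synth import SeriesSpec, ShellSpec, generate_series, \
    voxelize_labeled_shell


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see README for the schema)."""

    series: dict = field(default_factory=dict)
    tau: float = 100.0
    propagation_mode: str = "distance_modified"
    min_contact_faces: int = 1
    curvature_radius_multiplier: float = 0.75
    exclude_labels: tuple[int, ...] = ()
    sa_unit: str = "cm2"
    voxel_spacing_mm: float = 0.2
    valley_depth: float = 0.5
    noise_sd: float = 5.0
    rng_seed: int = 0
    out_dir: str = "run"
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_labels" in raw:
            raw["exclude_labels"] = tuple(raw["exclude_labels"])
        return cls(**raw)

    def to_series_spec(self) -> SeriesSpec:
        kw = dict(self.series)
        if "base_shell" in kw and isinstance(kw["base_shell"], dict):
            kw["base_shell"] = ShellSpec(**kw["base_shell"])
        kw.setdefault("rng_seed", self.rng_seed)
        return SeriesSpec(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.__dict__ | {
        "exclude_labels": list(config.exclude_labels)}))

    log: list[dict] = []
    series = config.to_series_spec()
    t0 = time.time()
    specimens, truth_table = generate_series(series)
    log.append({"stage": "generate", "seconds": round(time.time() - t0, 3),
                "n_specimens": len(specimens) or len(truth_table)})
    truth_table.to_csv(out / "ground_truth_series.csv", index=False)

    if not specimens:  # table-only run: fit directly on the truth table
        per_specimen = None
        table = truth_table
        from .allometry import fit_series
        fits = fit_series(table, sa_unit=config.sa_unit)
        box = pd.DataFrame()
    else:
        per_specimen = []
        for i, entry in enumerate(specimens):
            try:
                per_specimen.append(
                    _process_specimen(entry, i, config, out, log)
                )
            except Exception as exc:  # abort naming stage + specimen
                (out / "FAILED").write_text(
                    f"specimen {i}: {type(exc).__name__}: {exc}\n"
                )
                raise RuntimeError(f"pipeline failed at specimen {i}") from exc
        table, fits, box = summarize_series(per_specimen, sa_unit=config.sa_unit)
        box.to_csv(out / "normalized_boxplot_summaries.csv", index=False)

    table.to_csv(out / "series_table.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "config_sha256": _sha256(out / "config.yaml"),
        "artifacts": sorted(
            {p.name: _sha256(p) for p in out.glob("*.csv")}.items()
        ),
        "log": log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _process_specimen(entry, i: int, config: RunConfig, out: Path, log) -> dict:
    spec = entry["spec"]
    mesh = entry["mesh"]
    t0 = time.time()
    vol, truth_labels, seeds = voxelize_labeled_shell(
        mesh, spec, voxel_spacing_mm=config.voxel_spacing_mm,
        valley_depth=config.valley_depth, noise_sd=config.noise_sd,
    )
    mask = threshold_segment(vol, config.tau)
    labels = propagate_contours(vol, mask, seeds, mode=config.propagation_mode)
    rag = build_rag(labels, min_contact_faces=config.min_contact_faces)
    surface = extract_surface(labels)
    log.append({"stage": "segment", "specimen": i,
                "seconds": round(time.time() - t0, 3),
                "n_voxels": int(mask.sum()), "n_labels": len(rag.node_ids)})

    t0 = time.time()
    stats = compute_scute_stats(
        labels, rag, surface, exclude_labels=config.exclude_labels,
        curvature_radius_multiplier=config.curvature_radius_multiplier,
    )
    sa = carapace_surface_area(surface)
    stats = normalize_stats(stats, sa)
    keep = [l for l in rag.node_ids if l not in set(config.exclude_labels)]
    centers = np.array([rag.center(l) for l in keep])
    length, height, width = carapace_dimensions(centers)
    log.append({"stage": "measure", "specimen": i,
                "seconds": round(time.time() - t0, 3)})

    stats.to_csv(out / f"specimen_{i:03d}_scute_stats.csv", index=False)
    io.write_ply(out / f"specimen_{i:03d}_surface.ply", surface)
    io.write_rag(out / f"specimen_{i:03d}_rag.graphml", rag,
                 out / f"specimen_{i:03d}_rag_edges.csv")
    io.write_seeds(out / f"specimen_{i:03d}_seeds.json", seeds)
    if config.write_volumes:
        io.write_nrrd(out / f"specimen_{i:03d}_labels.nrrd", labels)
        io.write_nrrd(out / f"specimen_{i:03d}_intensity.nrrd", vol)

    return {
        "specimen": i, "stats": stats, "sa_mm2": sa,
        "length_mm": length, "height_mm": height, "width_mm": width,
    }


def report(run_dir) -> str:
    """Markdown summary of a completed run (written to report.md)."""
    run_dir = Path(run_dir)
    fits_path = run_dir / "fits.json"
    table_path = run_dir / "series_table.csv"
    if not fits_path.exists() or not table_path.exists():
        raise ValueError(f"{run_dir} is not a completed run directory")
    with open(fits_path) as fh:
        fits = json.load(fh)
    table = pd.read_csv(table_path)

    lines = ["# scutegrow run report", "", "## Per-specimen summary", ""]
    cols = list(table.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "---|" * len(cols))
    for _, row in table.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "## Scaling fits vs surface area", "",
              "| variable | slope | 95% CI | reference | verdict |",
              "|---|---|---|---|---|"]
    for name, f in fits.items():
        ref = f["isometry_reference"]
        if f["ci_low"] <= ref <= f["ci_high"]:
            verdict = "isometric"
        elif f["slope"] > ref:
            verdict = "positive allometry"
        else:
            verdict = "negative allometry"
        lines.append(
            f"| {name} | {f['slope']:.4f} | [{f['ci_low']:.4f}; "
            f"{f['ci_high']:.4f}] | {ref} | {verdict} |"
        )

    stats_files = sorted(run_dir.glob("specimen_*_scute_stats.csv"))
    if stats_files:
        lines += ["", "## Neighbor-count relative frequencies", "",
                  "| specimen | " + " | ".join(str(k) for k in range(3, 10)) + " |",
                  "|" + "---|" * 8]
        for p in stats_files:
            st = pd.read_csv(p)
            freq = st["n_neighbors"].value_counts(normalize=True)
            row = [p.stem.split("_")[1]]
            row += [f"{freq.get(k, 0.0):.2f}" for k in range(3, 10)]
            lines.append("| " + " | ".join(row) + " |")

    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
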