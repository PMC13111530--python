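"""End-to-end analysis pipeline: raster in, tables (and plots) out.

The eight stages run in order: load/clean -> regions + periods -> raster
metrics -> correlograms per region -> shape metrics -> metric
distributions -> classifications + fractions -> transitions and combined
combos.  Every output table is a headed CSV; a manifest JSON records the
configuration, output hashes and elapsed time.  Correlograms are cached
(keyed by a hash of the inputs that determine them) so that re-runs that
only change metric or classification settings skip the expensive stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, raster_metrics, shape_metrics
from .correlogram import Correlogram, CorrelogramSpec, correlogram_set, is_sparse, make_bins
from .io import CleaningSpec, Recording, TreatmentEvent, apply_cleaning, load_recording
from .regions import AnalysisRegion, assign_periods, auto_regions, manual_regions
from .shape_metrics import MetricParams, compute_metrics

__all__ = ["RunConfig", "run_pipeline", "cache_or_recompute", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, declaratively."""

    input_path: str
    output_dir: str
    duration: float | None = None
    excluded_windows: tuple = ()
    removed_units: tuple = ()
    region_length_s: float | None = 420.0
    regions: tuple = ()              # manual (start, end, label) triples
    treatments: tuple = ()           # (time_s, label) pairs
    range_s: float = 1.0
    bin_width_s: float = 0.001
    reference_subset: tuple | None = None
    sparsity_threshold: int = 0
    alpha: float = 0.05
    smooth_window: int = 5
    chi2_variant: str = "pearson"
    max_peak_class: int = 4
    peak_time_mode: str = "timescale"
    include_autocorrelograms: bool = False
    grouping: str = "period"         # "period" | "region"
    plots: bool = False
    cache_dir: str | None = None
    save_counts: bool = False        # also dump per-pair binned counts (npz)

    def correlogram_spec(self) -> CorrelogramSpec:
        return CorrelogramSpec(self.range_s, self.bin_width_s, self.reference_subset)

    def metric_params(self) -> MetricParams:
        return MetricParams(
            alpha=self.alpha,
            smooth_window=self.smooth_window,
            chi2_variant=self.chi2_variant,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON config file into a RunConfig (round-trip safe)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("excluded_windows", "removed_units", "regions", "treatments"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
    if raw.get("reference_subset") is not None:
        raw["reference_subset"] = tuple(raw["reference_subset"])
    return RunConfig(**raw)


def _correlogram_cache_key(config: RunConfig, rec: Recording) -> str:
    """Hash of everything that determines the binned correlograms."""
    payload = {
        "units": rec.unit_ids,
        "n_events": [len(t) for t in rec.trains],
        "duration": rec.duration,
        "excluded_windows": list(map(list, config.excluded_windows)),
        "removed_units": list(config.removed_units),
        "region_length_s": config.region_length_s,
        "regions": list(map(list, config.regions)),
        "range_s": config.range_s,
        "bin_width_s": config.bin_width_s,
        "reference_subset": (
            None if config.reference_subset is None else list(config.reference_subset)
        ),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cache_or_recompute(config: RunConfig, rec: Recording) -> tuple[bool, Path | None]:
    """Decide whether cached correlograms can be reused.

    Returns (reuse, cache_file).  Correlograms are reused iff the inputs,
    cleaning, region definitions and correlogram geometry are unchanged
    (hash match); metric/classification stages are always recomputed from
    the (possibly cached) correlograms.
    """
    if config.cache_dir is None:
        return False, None
    cache_dir = Path(config.cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _correlogram_cache_key(config, rec)
    cache_file = cache_dir / f"correlograms_{key}.npz"
    return cache_file.exists(), cache_file


def _build_regions(config: RunConfig, rec: Recording) -> list[AnalysisRegion]:
    if config.regions:
        return manual_regions(config.regions)
    if config.region_length_s is None:
        raise ValueError("need region_length_s or manual regions")
    return auto_regions(rec.duration, config.region_length_s)


def _all_correlograms(
    config: RunConfig, rec: Recording, regions: list[AnalysisRegion]
) -> list[Correlogram]:
    spec = config.correlogram_spec()
    reuse, cache_file = cache_or_recompute(config, rec)
    if reuse:
        return _load_correlograms(cache_file, spec, regions)
    cgs = [cg for region in regions for cg in correlogram_set(rec, region, spec)]
    if cache_file is not None:
        _save_correlograms(cache_file, cgs)
    return cgs


def _save_correlograms(path: Path, cgs: list[Correlogram]) -> None:
    meta = np.array(
        [(c.ref_id, c.cmp_id, c.region_index, c.n_ref, c.n_cmp) for c in cgs],
        dtype=object,
    )
    counts = np.stack([c.counts for c in cgs]) if cgs else np.empty((0, 0))
    np.savez_compressed(path, meta=meta, counts=counts)


def _load_correlograms(
    path: Path, spec: CorrelogramSpec, regions: list[AnalysisRegion]
) -> list[Correlogram]:
    data = np.load(path, allow_pickle=True)
    _, centers = make_bins(spec)
    out = []
    for row, counts in zip(data["meta"], data["counts"]):
        ref_id, cmp_id, region_index, n_ref, n_cmp = row
        out.append(
            Correlogram(
                str(ref_id), str(cmp_id), int(region_index), centers,
                counts.astype(np.int64), int(n_ref), int(n_cmp),
            )
        )
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; return the output directory.

    Deterministic: identical config + input give byte-identical tables.
    """
    t0 = time.monotonic()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "outputs": {}}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / name
        df.to_csv(path, index=index)
        written.append(path)

    stage = "load/clean"
    try:
        rec = load_recording(config.input_path, duration=config.duration)
        if config.treatments:
            rec = Recording(
                rec.trains, rec.duration,
                tuple(TreatmentEvent(t, lab) for t, lab in config.treatments),
                rec.source,
            )
        if config.excluded_windows or config.removed_units:
            rec = apply_cleaning(
                rec,
                CleaningSpec(tuple(map(tuple, config.excluded_windows)),
                             tuple(config.removed_units)),
            )
        manifest["stages"].append(stage)

        stage = "regions"
        regions = _build_regions(config, rec)
        periods = assign_periods(regions, list(rec.treatments))
        emit("regions.csv", pd.DataFrame(
            [
                {"region_index": r.index, "start_s": r.start, "end_s": r.end,
                 "label": r.label, "period": periods.period_of(r.index)}
                for r in regions
            ]
        ))
        manifest["stages"].append(stage)

        stage = "raster_metrics"
        emit("firing_counts.csv", raster_metrics.firing_counts(rec, regions, periods))
        try:
            hist = raster_metrics.isi_histogram(list(rec.trains))
            emit("isi_hist.csv", pd.DataFrame(
                {"bin_lo_s": hist.bin_edges[:-1], "bin_hi_s": hist.bin_edges[1:],
                 "prob": hist.probs}
            ))
        except ValueError:
            pass  # no unit has two events; skip the ISI table
        trace = raster_metrics.rate_trace(rec)
        rt = trace.counts.copy()
        rt.index.name = "unit_id"
        emit("rate_trace.csv", rt, index=True)
        emit("rate_trace_summary.csv", pd.DataFrame(
            {"minute": range(len(trace.mean)), "mean": trace.mean, "sd": trace.sd}
        ))
        manifest["stages"].append(stage)

        stage = "correlograms"
        cgs = _all_correlograms(config, rec, regions)
        emit("correlograms.csv", pd.DataFrame(
            [
                {"region_index": c.region_index, "ref_id": c.ref_id,
                 "cmp_id": c.cmp_id, "n_ref": c.n_ref, "n_cmp": c.n_cmp,
                 "total": c.total,
                 "sparse_flag": is_sparse(c, config.sparsity_threshold)}
                for c in cgs
            ]
        ))
        if config.save_counts:
            _save_correlograms(out_dir / "correlogram_counts.npz", cgs)
        manifest["stages"].append(stage)

        stage = "shape_metrics"
        params = config.metric_params()
        metric_rows = []
        for c in cgs:
            sm = compute_metrics(c, params, config.sparsity_threshold)
            metric_rows.append((c, sm))
        emit("metrics.csv", pd.DataFrame(
            [
                {
                    "region_index": c.region_index, "ref_id": c.ref_id,
                    "cmp_id": c.cmp_id, "total": c.total, "n_pairs": c.n_pairs,
                    "chi2": sm.chi2 if sm else np.nan,
                    "p_value": sm.p_value if sm else np.nan,
                    "uniform": sm.uniform if sm else None,
                    "expected_count_warning": sm.expected_count_warning if sm else None,
                    "peak_count": sm.peak_count if sm else None,
                    "peak_times": ";".join(f"{t:.6f}" for t in sm.peak_times) if sm else "",
                    "area_left": sm.area_left if sm else np.nan,
                    "sparse_flag": sm is None,
                }
                for c, sm in metric_rows
            ]
        ))
        manifest["stages"].append(stage)

        stage = "classification"
        records = classify.classify_records(
            [(c.region_index, c.ref_id, c.cmp_id, sm) for c, sm in metric_rows],
            alpha=config.alpha,
            max_peak_class=config.max_peak_class,
            peak_time_mode=config.peak_time_mode,
            range_s=config.range_s,
        )
        emit("classes.csv", pd.DataFrame(
            [
                {"region_index": r.region_index, "ref_id": r.ref_id,
                 "cmp_id": r.cmp_id, "uniformity_class": r.uniformity_class,
                 "peak_class": r.peak_class, "lf_class": r.lf_class,
                 "peak_time_classes": ";".join(r.peak_time_classes)}
                for r in records
            ]
        ))
        emit("fractions.csv", classify.class_fractions(
            records, config.include_autocorrelograms
        ))
        manifest["stages"].append(stage)

        stage = "transitions"
        step = "period" if config.grouping == "period" else "region"
        rows = []
        for scheme in ("uniformity_class", "peak_class", "lf_class"):
            tables = classify.transition_probabilities(
                records, scheme=scheme, step=step,
                periods=periods if step == "period" else None,
                include_autocorrelograms=config.include_autocorrelograms,
            )
            for tab in tables:
                for src in tab.matrix.index:
                    if tab.support[src] == 0:
                        continue
                    for dst in tab.matrix.columns:
                        rows.append(
                            {"scheme": scheme, "grouping": tab.grouping,
                             "from_class": src, "to_class": dst,
                             "probability": tab.matrix.loc[src, dst],
                             "support": tab.support[src],
                             "skipped": tab.skipped}
                        )
        emit(f"transitions_{step}.csv", pd.DataFrame(rows))
        manifest["stages"].append(stage)

        stage = "combos"
        combos = classify.combined_combo_table(
            records, config.max_peak_class,
            grouping=periods.mapping if config.grouping == "period" else None,
            include_autocorrelograms=config.include_autocorrelograms,
        )
        emit("combos.csv", combos.reset_index())
        manifest["stages"].append(stage)

        if config.plots:
            stage = "plots"
            from .plots import plot_suite

            manifest["plots"] = [
                str(p) for p in plot_suite(out_dir, rec.unit_ids)
            ]
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for path in written:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["outputs"][path.name] = digest
    manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
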