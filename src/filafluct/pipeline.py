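"""End-to-end orchestration: simulate -> [render/segment] -> stats -> compare -> clusters.

A run is described by a YAML config (see ``default_config``): named
simulated runs (or an external cells CSV), per-stage parameter blocks and a
single global seed.  The global seed deterministically spawns per-stage,
per-run sub-seeds, so any stage can be re-run in isolation with identical
results; every seed and parameter lands in ``manifest.json``.

Numeric outputs (CSV/JSON) are byte-identical across repeated runs with the
same config and seed.  Plots are artifacts only — nothing downstream ever
reads them.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import cluster_analysis as ca
from . import filament_stats as fs
from . import histogram_compare as hc
from . import io as fio
from . import segmentation as seg
from . import synthetic_data as sd
from .datatypes import FilamentSet

__all__ = ["RunConfig", "PipelineStageError", "default_config",
           "validate_config", "run_pipeline"]

_KNOWN_STAGES = ("simulate", "render", "segment", "stats", "compare",
                 "clusters", "report")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Parsed pipeline configuration (thin wrapper over the YAML dict)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as e:
            raise ValueError(f"unparseable YAML config {path}: {e}") from e
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls(data)

    def get(self, key, default=None):
        return self.raw.get(key, default)


def default_config() -> dict:
    """The shipped demo configuration: two simulated strains, full analysis."""
    return {
        "seed": 1,
        "output_dir": "out",
        "stages": ["simulate", "render", "segment", "stats", "compare",
                   "clusters", "report"],
        "runs": {
            "wt_like": {
                "n_filaments": 300,
                "length_law": ["uniform", 8, 40],
                "baseline_mean": 13.0,
                "filament_cv": 0.074,
                "within_kernel": [1.0, 1.0, 1.0],
                "innovation_shape": 4.0,
                "cell_noise_sd": 0.5,
            },
            "broad_like": {
                "n_filaments": 300,
                "length_law": ["uniform", 8, 40],
                "baseline_mean": 18.0,
                "filament_cv": 0.2,
                "within_kernel": [1.0, 1.0, 1.0, 0.6],
                "innovation_shape": 1.5,
                "cell_noise_sd": 0.5,
            },
        },
        "render": {"runs": ["wt_like"], "max_filaments": 8},
        "segment": {},
        "stats": {"n_max": 5, "n_permutations": 10, "min_length": 8},
        "compare": {"pairs": [["wt_like", "broad_like"]], "bin_width": 1.0,
                    "n_boot": 500},
        "clusters": {
            "percentile": 0.15,
            "null_model": {"n_strings": 1000, "string_length": 20, "p": 0.15},
            "n_boot": 1000,
        },
    }


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_config(config: RunConfig | dict) -> list[str]:
    """Check every parameter block; returns a list of violations (empty = ok)."""
    cfg = config.raw if isinstance(config, RunConfig) else config
    v: list[str] = []

    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        v.append("seed: must be a non-negative integer")

    stages = cfg.get("stages", [])
    if not stages:
        v.append("stages: must list at least one stage")
    for s in stages:
        if s not in _KNOWN_STAGES:
            v.append(f"stages: unknown stage '{s}'")

    runs = cfg.get("runs", {})
    if "simulate" in stages and not runs:
        v.append("runs: simulate stage requires at least one run block")
    for name, block in (runs or {}).items():
        try:
            _trace_params(name, block, seed=0)
        except (ValueError, TypeError) as e:
            v.append(f"runs.{name}: {e}")

    if "segment" in stages:
        try:
            seg.SegmentationParams(**cfg.get("segment", {}) or {})
        except (ValueError, TypeError) as e:
            v.append(f"segment: {e}")
        if "render" not in stages:
            v.append("segment: requires the render stage")

    st = cfg.get("stats", {}) or {}
    if st.get("n_max", 5) < 1:
        v.append("stats.n_max: must be >= 1")
    if st.get("n_permutations", 10) < 1:
        v.append("stats.n_permutations: must be >= 1")
    if st.get("min_length", 8) < 2:
        v.append("stats.min_length: must be >= 2")

    cmp_cfg = cfg.get("compare", {}) or {}
    for pair in cmp_cfg.get("pairs", []):
        if len(pair) != 2 or any(p not in runs for p in pair):
            v.append(f"compare.pairs: {pair} does not name two known runs")
    bw = cmp_cfg.get("bin_width")
    if bw is not None and bw <= 0:
        v.append("compare.bin_width: must be positive")

    cl = cfg.get("clusters", {}) or {}
    pct = cl.get("percentile", 0.15)
    if not 0 < pct < 1:
        v.append("clusters.percentile: must be in (0, 1)")
    nm = cl.get("null_model", {}) or {}
    try:
        ca.BernoulliSimParams(**{**{"n_strings": 1000, "string_length": 20,
                                    "p": 0.15}, **nm})
    except (ValueError, TypeError) as e:
        v.append(f"clusters.null_model: {e}")

    cells_csv = cfg.get("cells_csv")
    if cells_csv is not None and not Path(cells_csv).exists():
        v.append(f"cells_csv: input file not found: {cells_csv}")
    if "stats" in stages and "simulate" not in stages and cells_csv is None:
        v.append("stats: needs either the simulate stage or cells_csv input")
    return v


def _trace_params(name: str, block: dict, seed) -> sd.TraceGenParams:
    block = dict(block or {})
    if "length_law" in block:
        block["length_law"] = tuple(block["length_law"])
    if "within_kernel" in block:
        block["within_kernel"] = tuple(block["within_kernel"])
    return sd.TraceGenParams(**block, seed=seed, run_id=name)


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def _spawn_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    """Deterministic per-label sub-seeds (< 2**31) from the global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    return {
        lab: int(c.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for lab, c in zip(labels, children)
    }


def run_pipeline(config: RunConfig | dict, output_dir=None) -> dict:
    """Execute the configured stages in order; returns the report dict.

    Writes cells CSVs, curve CSVs, comparison/cluster JSONs, a manifest
    with versions/seeds/parameters, and (report stage) PNG plots into the
    output directory.  Any stage failure aborts with a stage-tagged
    :class:`PipelineStageError`; partial outputs are kept and the manifest
    records the failed stage.
    """
    cfg = config.raw if isinstance(config, RunConfig) else config
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))

    out = Path(output_dir or cfg.get("output_dir", "out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    seed = int(cfg.get("seed", 0))
    run_names = sorted(cfg.get("runs", {}))
    seed_labels = (
        [f"simulate:{n}" for n in run_names]
        + [f"render:{n}" for n in run_names]
        + ["stats", "compare", "clusters"]
    )
    sub_seeds = _spawn_seeds(seed, seed_labels)

    try:
        version = importlib.metadata.version("filafluct")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest: dict = {
        "package": "filafluct",
        "version": version,
        "seed": seed,
        "sub_seeds": sub_seeds,
        "config": cfg,
        "stages_completed": [],
    }
    report: dict = {}
    fsets: dict[str, FilamentSet] = {}
    truths: dict[str, sd.TraceGenTruth] = {}
    rendered: dict[str, tuple[np.ndarray, sd.GroundTruth]] = {}

    def _finish(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        fio.write_json(manifest, out / "manifest.json")

    try:
        for stage in stages:
            if stage == "simulate":
                for name in run_names:
                    params = _trace_params(
                        name, cfg["runs"][name], sub_seeds[f"simulate:{name}"]
                    )
                    fset, truth = sd.generate_traces(params)
                    fsets[name] = fset
                    truths[name] = truth
                    fio.write_cells_csv(fset, out / f"cells_{name}.csv")
                report["simulate"] = {
                    name: {
                        "n_filaments": len(fsets[name]),
                        "n_cells": fsets[name].n_cells,
                        "expected_ratio": truths[name].expected_ratio,
                        "kernel_autocorrelation":
                            truths[name].kernel_autocorrelation.tolist(),
                    }
                    for name in run_names
                }

            elif stage == "render":
                rcfg = cfg.get("render", {}) or {}
                names = rcfg.get("runs", run_names)
                cap = int(rcfg.get("max_filaments", 8))
                for name in names:
                    if name not in fsets:
                        raise FileNotFoundError(
                            f"render: no simulated traces for run '{name}'"
                        )
                    subset = FilamentSet(
                        [replace_trace_len(t) for t in fsets[name].traces[:cap]],
                        run_id=name,
                    )
                    iparams = sd.ImageGenParams(
                        image_size=(
                            32 + cap * 16,
                            48 + 16 * max(len(t) for t in subset) ,
                        ),
                        path_curvature=0.3,
                        seed=sub_seeds[f"render:{name}"],
                    )
                    img, truth = sd.generate_images(iparams, subset)
                    rendered[name] = (img, truth)
                    fio.write_image_tiff(img, out / f"image_{name}.tif")
                    fio.write_label_tiff(
                        truth.label_image, out / f"labels_true_{name}.tif"
                    )
                    fio.write_json(
                        {"filament_assignments": truth.filament_assignments},
                        out / f"assignments_true_{name}.json",
                    )

            elif stage == "segment":
                sparams = seg.SegmentationParams(**(cfg.get("segment", {}) or {}))
                seg_report = {}
                for name, (img, truth) in rendered.items():
                    labels, cells = seg.segment_cells(img, sparams)
                    cells = seg.order_into_filaments(cells, sparams)
                    fio.write_label_tiff(labels, out / f"labels_seg_{name}.tif")
                    fio.write_cell_records_csv(
                        cells, out / f"cells_seg_{name}.csv", run_id=name
                    )
                    matches = seg.match_cells(labels, truth.label_image)
                    seg_report[name] = {
                        "n_true": truth.n_cells,
                        "n_segmented": len(cells),
                        "n_matched": len(matches),
                        "recovery": len(matches) / max(truth.n_cells, 1),
                    }
                report["segment"] = seg_report

            elif stage == "stats":
                if not fsets:
                    path = cfg.get("cells_csv")
                    if path is None or not Path(path).exists():
                        raise FileNotFoundError(
                            f"stats: cells CSV input not found: {path}"
                        )
                    fsets.update(fio.read_cells_csv_multi(path))
                st = cfg.get("stats", {}) or {}
                n_max = int(st.get("n_max", 5))
                n_perm = int(st.get("n_permutations", 10))
                min_len = int(st.get("min_length", 8))
                rng = np.random.default_rng(sub_seeds["stats"])
                stats_report = {}
                for name in sorted(fsets):
                    fset = seg.filter_filaments(fsets[name], min_len)
                    fsets[name] = fset
                    corrected, raw, _bias = fs.autocorrelation_corrected(
                        fset, n_max, n_permutations=n_perm, seed=rng,
                        return_components=True,
                    )
                    pairs = fs.neighbor_pairs(fset)
                    dec = fs.noise_decomposition(fset)
                    fio.write_curve_csv(corrected, out / f"curve_{name}.csv")
                    fio.write_curve_csv(raw, out / f"curve_raw_{name}.csv")
                    stats_report[name] = {
                        "n_filaments": len(fset),
                        "n_cells": fset.n_cells,
                        "population_noise": fs.population_noise(fset),
                        "between": dec.between,
                        "within_avg": dec.within_avg,
                        "between_within_ratio": dec.ratio,
                        "pearson_neighbors": pairs.pearson_r,
                        "g_corrected": corrected.g.tolist(),
                        "g_raw": raw.g.tolist(),
                        "g_se": corrected.se.tolist(),
                    }
                report["stats"] = stats_report
                fio.write_json(stats_report, out / "noise_report.json")

            elif stage == "compare":
                ccfg = cfg.get("compare", {}) or {}
                bw = ccfg.get("bin_width")
                n_boot = int(ccfg.get("n_boot", 500))
                rng = np.random.default_rng(sub_seeds["compare"])
                cmp_report = {}
                for a, b in ccfg.get("pairs", []):
                    va, vb = fsets[a].pooled_values(), fsets[b].pooled_values()
                    ha, hb = hc.build_histogram_pair(va, vb, bin_width=bw)
                    d_emd = hc.emd(ha, hb)
                    d_ks = hc.ks_distance(ha, hb)

                    def _emd_stat(x, y):
                        hx, hy = hc.build_histogram_pair(x, y, bin_width=bw)
                        return hc.emd(hx, hy).statistic

                    se = hc.bootstrap_se([va, vb], _emd_stat, n_boot=n_boot,
                                         seed=rng)
                    cmp_report[f"{a}_vs_{b}"] = {
                        "emd": d_emd.statistic,
                        "emd_se": se,
                        "ks": d_ks.statistic,
                        "n_bins": ha.b,
                    }
                report["compare"] = cmp_report
                fio.write_json(cmp_report, out / "compare.json")

            elif stage == "clusters":
                clcfg = cfg.get("clusters", {}) or {}
                bparams = ca.BinarizationParams(
                    percentile=float(clcfg.get("percentile", 0.15))
                )
                nm = {**{"n_strings": 1000, "string_length": 20, "p": 0.15},
                      **(clcfg.get("null_model", {}) or {})}
                n_boot = int(clcfg.get("n_boot", 1000))
                rng = np.random.default_rng(sub_seeds["clusters"])
                cl_report = {}
                sizes_by_run = {}
                for name in sorted(fsets):
                    bits, thr = ca.binarize(fsets[name], bparams)
                    sizes = np.concatenate(
                        [ca.cluster_sizes(bf) for bf in bits]
                    ) if bits else np.empty(0, int)
                    sizes_by_run[name] = sizes
                    null = ca.BernoulliSimParams(
                        **nm, seed=int(rng.integers(2 ** 31))
                    )
                    res = ca.compare_to_independent(
                        sizes, null, n_boot=n_boot, seed=rng
                    )
                    cl_report[name] = {
                        "threshold": thr,
                        "n_clusters": int(sizes.size),
                        "mean_cluster_size": float(sizes.mean()) if sizes.size else None,
                        "emd_vs_independent": res.statistic,
                        "emd_se": res.se,
                    }
                # pairwise chi2 between runs' cluster-size histograms
                names = sorted(sizes_by_run)
                chi2_report = {}
                for i, a in enumerate(names):
                    for b in names[i + 1:]:
                        sa, sb = sizes_by_run[a], sizes_by_run[b]
                        if sa.size == 0 or sb.size == 0:
                            continue
                        top = int(max(sa.max(), sb.max()))
                        res = hc.cluster_chi2(
                            ca.cluster_size_histogram(sa, max_size=top),
                            ca.cluster_size_histogram(sb, max_size=top),
                        )
                        chi2_report[f"{a}_vs_{b}"] = {
                            "X2": res.statistic, "p_value": res.p_value,
                            "dof": res.dof,
                        }
                report["clusters"] = {"per_run": cl_report,
                                      "pairwise_chi2": chi2_report}
                fio.write_json(report["clusters"], out / "clusters.json")

            elif stage == "report":
                _make_plots(fsets, report, out)

            _finish(stage)
    except PipelineStageError:
        raise
    except BaseException as e:
        manifest["failed_stage"] = stage
        fio.write_json(manifest, out / "manifest.json")
        raise PipelineStageError(stage, e) from e

    fio.write_json(report, out / "report.json")
    return report


def replace_trace_len(t):
    """Cap a trace at 14 cells so rendered rows stay compact."""
    from .datatypes import FilamentTrace

    if len(t) <= 14:
        return t
    return FilamentTrace(t.values[:14].copy(), t.filament_id, t.run_id)


def _make_plots(fsets: dict[str, FilamentSet], report: dict, out: Path) -> None:
    """Publication-style overview plots (artifacts only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if fsets:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for name in sorted(fsets):
            v = fsets[name].pooled_values()
            ax.hist(v, bins=40, density=True, alpha=0.5, label=name)
        ax.set_xlabel("fluorescence (a.u.)")
        ax.set_ylabel("frequency")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fluorescence_histograms.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 4))
        for name in sorted(fsets):
            pairs = fs.neighbor_pairs(fsets[name])
            ax.plot(pairs.f_n, pairs.f_n1, ".", ms=2, alpha=0.3,
                    label=f"{name} (r={pairs.pearson_r:.2f})")
        ax.set_xlabel("f(n)")
        ax.set_ylabel("f(n+1)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "neighbor_scatter.png", dpi=120)
        plt.close(fig)

    if "stats" in report:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for name, blk in sorted(report["stats"].items()):
            g = np.asarray(blk["g_corrected"])
            se = np.asarray(blk["g_se"])
            ax.errorbar(np.arange(g.size), g, yerr=se, marker="o",
                        capsize=3, label=name)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("cell distance n")
        ax.set_ylabel("g(n)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "autocorrelation.png", dpi=120)
        plt.close(fig)
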