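"""Config-driven orchestration of the full delimitation analysis.

One YAML config describes the inputs (per-aspect TPS + sliders + labels,
barcode FASTA) and every under-specified analysis choice (sliding mode,
dimension-retention rule, replicate policy, nesting, permutation counts,
seeds); :func:`run_pipeline` then runs, per anatomical aspect,

    GPA -> tangent check -> Procrustes ANOVA -> relative warps ->
    between-group PCA (+ deformation grids) -> CVA + jackknife confusion
    matrix -> pairwise PERMANOVA (Bonferroni)

and, for barcodes, distance matrix -> threshold partitions -> single-linkage
dendrogram.  Every stage writes its table under the output directory and a
JSON summary collects the headline statistics, each tagged with the
producing stage and the seed.  Any stage failure aborts with the stage name
and offending input.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .barcode_cluster import merge_profile, objective_cluster, p_distance_matrix
from .discriminate import cva, jackknife_classify, pairwise_permanova
from .io_formats import DatasetError, ShapeDataset, attach_labels
from .shape_variation import between_group_pca, procrustes_anova, relative_warps
from .superimpose import AlignedDataset, gpa, tangent_check
from .tps_warp import fit_tps, jacobian_grid

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cryptomorph.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class AspectInput:
    tps: str
    labels: str
    sliders: str | None = None


@dataclass
class PipelineConfig:
    """All inputs and analysis choices for one pipeline run."""

    output_dir: str
    aspects: dict = field(default_factory=dict)  # name -> AspectInput
    fasta: str | None = None
    thresholds: list[float] = field(default_factory=lambda: [0.02, 0.03, 0.04, 0.05])
    seed: int = 0
    n_perm_anova: int = 999
    n_perm_permanova: int = 9999
    retain: object = "variance99"
    replicate_policy: str = "all"  # "all" keeps every digitized configuration
    slide_mode: str = "bending_energy"
    nest_site_in_species: bool = True
    flip_y: bool = False
    grid_resolution: int = 24
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.aspects = {
            name: a if isinstance(a, AspectInput) else AspectInput(**a)
            for name, a in self.aspects.items()
        }
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise DatasetError(f"threshold {t} outside [0, 1]")
        for name, a in self.aspects.items():
            for p in (a.tps, a.labels, a.sliders):
                if p is not None and not Path(p).exists():
                    raise DatasetError(f"aspect {name!r}: input file missing: {p}")
        if self.fasta is not None and not Path(self.fasta).exists():
            raise DatasetError(f"barcode FASTA missing: {self.fasta}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage(name: str, subject: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s [%s] ...", name, subject)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed on {subject!r}: {exc}") from exc
            log.info("stage %s [%s] done in %.2fs", name, subject, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def _average_replicates(aligned: AlignedDataset) -> AlignedDataset:
    """Average aligned coordinates over replicates of each specimen."""
    if aligned.labels is None:
        raise DatasetError("replicate averaging requires a label table")
    lab = aligned.labels.loc[aligned.ids]
    specimen = [
        i[: -len("_" + r)] if i.endswith("_" + str(r)) else i
        for i, r in zip(aligned.ids, lab["replicate_id"])
    ]
    df = pd.DataFrame({"specimen": specimen}, index=aligned.ids)
    order: list[str] = list(dict.fromkeys(specimen))
    coords, ids, rows = [], [], []
    for sp in order:
        members = [i for i, s in zip(aligned.ids, specimen) if s == sp]
        sel = [aligned.ids.index(i) for i in members]
        coords.append(aligned.coords[sel].mean(axis=0))
        ids.append(sp)
        row = lab.loc[members[0]].to_dict()
        row.pop("replicate_id", None)
        rows.append(row)
    del df
    labels = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    labels["replicate_id"] = "mean"
    return AlignedDataset(
        coords=np.stack(coords),
        centroid_sizes=np.ones(len(ids)),
        consensus=aligned.consensus,
        n_iterations=aligned.n_iterations,
        converged_delta=aligned.converged_delta,
        converged=aligned.converged,
        tangent_projected=aligned.tangent_projected,
        preshapes=None,
        ids=ids,
        labels=labels,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the JSON summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    summary: dict = {"seed": config.seed, "aspects": {}, "barcode": None}
    try:
        for name, aspect in config.aspects.items():
            summary["aspects"][name] = _run_aspect(name, aspect, config, out)
        if config.fasta is not None:
            summary["barcode"] = _run_barcode(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    return summary


def _run_aspect(name: str, aspect: AspectInput, config: PipelineConfig, out: Path) -> dict:
    res: dict = {"stage_seed": config.seed}
    adir = out / name
    adir.mkdir(exist_ok=True)

    with _stage("read_tps", aspect.tps):
        dataset = io_formats.read_tps(aspect.tps, flip_y=config.flip_y)
        labels = io_formats.read_labels(aspect.labels)
        dataset = attach_labels(dataset, labels)
    sliders = None
    if aspect.sliders is not None:
        with _stage("read_sliders", aspect.sliders):
            sliders = io_formats.read_sliders(aspect.sliders, dataset.k)

    with _stage("gpa", name):
        aligned = gpa(dataset, sliders=sliders, slide_mode=config.slide_mode)
        _write_aligned(aligned, adir)
    with _stage("tangent_check", name):
        tc = tangent_check(aligned)
        res["tangent"] = {"slope": tc.slope, "correlation": tc.correlation, "stage": "tangent_check"}

    with _stage("procrustes_anova", name):
        table = procrustes_anova(
            aligned,
            n_perm=config.n_perm_anova,
            seed=config.seed,
            nest_site_in_species=config.nest_site_in_species,
        )
        table.table.to_csv(adir / "procrustes_anova.csv")
        res["anova"] = {
            "stage": "procrustes_anova",
            "rows": {
                src: {
                    "percent_ss": float(r["percent_ss"]),
                    "F": None if np.isnan(r["F"]) else float(r["F"]),
                    "p": None if np.isnan(r["p"]) else float(r["p"]),
                }
                for src, r in table.table.iterrows()
            },
        }

    analysed = aligned
    if config.replicate_policy == "mean":
        with _stage("average_replicates", name):
            analysed = _average_replicates(aligned)
    elif config.replicate_policy != "all":
        raise PipelineError(f"unknown replicate policy {config.replicate_policy!r}")

    with _stage("relative_warps", name):
        warps = relative_warps(analysed)
        pd.DataFrame(warps.scores, index=analysed.ids).to_csv(adir / "warp_scores.csv")
    groups = analysed.label_vector("species")

    with _stage("between_group_pca", name):
        pca = between_group_pca(analysed.flat(), groups)
        pd.DataFrame(pca.scores, index=analysed.ids).to_csv(adir / "bgpca_scores.csv")
        res["bgpca"] = {
            "stage": "between_group_pca",
            "percent_variance": [float(v) for v in pca.percent_variance],
            "percent_total": [float(v) for v in pca.percent_total],
            "top5_percent": float(np.sum(pca.percent_variance[:5])),
        }

    with _stage("deformation_grids", name):
        k = analysed.k
        consensus = analysed.consensus
        grids = {}
        for ax in range(min(2, pca.axes.shape[1])):
            lo, hi = pca.scores[:, ax].min(), pca.scores[:, ax].max()
            for label, c in (("neg", lo), ("pos", hi)):
                target = (consensus.ravel() + c * pca.axes[:, ax]).reshape(k, 2)
                warp = fit_tps(consensus, target)
                grid = jacobian_grid(warp, (config.grid_resolution, config.grid_resolution))
                gname = f"pc{ax + 1}_{label}"
                pd.DataFrame(grid.jacobian, index=grid.y, columns=grid.x).to_csv(
                    adir / f"grid_{gname}.csv"
                )
                grids[gname] = {
                    "score": float(c),
                    "bending_energy": warp.bending_energy,
                    "det_range": [float(grid.jacobian.min()), float(grid.jacobian.max())],
                }
                if config.make_plots:
                    from .viz import plot_deformation_grid

                    plot_deformation_grid(grid, warp, adir / f"grid_{gname}.png")
        res["grids"] = {"stage": "deformation_grids", **grids}

    with _stage("cva", name):
        fit = cva(warps.scores, groups, retain=config.retain)
        pd.DataFrame(fit.scores, index=analysed.ids).to_csv(adir / "cva_scores.csv")
        res["cva"] = {
            "stage": "cva",
            "percent_variance": [float(v) for v in fit.percent_variance],
            "cv1_plus_cv2_percent": float(np.sum(fit.percent_variance[:2])),
            "retained": fit.retained,
        }
        if config.make_plots:
            from .viz import plot_scores

            plot_scores(fit.scores, groups, adir / "cva_scatter.png", "CV")
    with _stage("jackknife_classify", name):
        cm = jackknife_classify(warps.scores, groups, retain=config.retain)
        cm.to_frame().to_csv(adir / "confusion_matrix.csv")
        res["jackknife"] = {
            "stage": "jackknife_classify",
            "accuracy_percent": cm.accuracy,
            "groups": [str(gr) for gr in cm.groups],
        }

    with _stage("pairwise_permanova", name):
        tests = pairwise_permanova(
            warps.scores, groups, n_perm=config.n_perm_permanova, seed=config.seed
        )
        tests.f_values.to_csv(adir / "permanova_F.csv")
        tests.p_corrected.to_csv(adir / "permanova_p_bonferroni.csv")
        res["permanova"] = {
            "stage": "pairwise_permanova",
            "n_perm": tests.n_perm,
            "max_F": float(np.nanmax(tests.f_values.values)),
            "n_significant_pairs": int(
                (tests.p_corrected.values[np.triu_indices(len(tests.groups), 1)] < 0.05).sum()
            ),
        }
    return res


def _run_barcode(config: PipelineConfig, out: Path) -> dict:
    bdir = out / "barcode"
    bdir.mkdir(exist_ok=True)
    with _stage("read_fasta", str(config.fasta)):
        seqs = io_formats.read_fasta(config.fasta)
    with _stage("p_distance_matrix", "barcode"):
        dist = p_distance_matrix(seqs)
        dist.to_frame().to_csv(bdir / "p_distances.csv")
        (bdir / "p_distances.phy").write_text(dist.to_phylip())
    partitions = {}
    with _stage("objective_cluster", "barcode"):
        for t in config.thresholds:
            part = objective_cluster(dist, t)
            pd.Series(part.assignment, name="cluster").rename_axis("id").to_csv(
                bdir / f"partition_{t:.3f}.csv"
            )
            partitions[f"{t:g}"] = part.n_clusters
    with _stage("merge_profile", "barcode"):
        profile = merge_profile(dist)
        (bdir / "dendrogram.nwk").write_text(profile.to_newick(percent=True))
        heights = profile.merge_heights()
    off = ~np.eye(dist.n, dtype=bool)
    return {
        "stage": "barcode_cluster",
        "n_sequences": seqs.n,
        "alignment_length": seqs.length,
        "clusters_per_threshold": partitions,
        "max_merge_height_percent": float(100.0 * heights.max()),
        "max_p_distance_percent": float(100.0 * np.nanmax(dist.matrix[off])),
    }


def _write_aligned(aligned: AlignedDataset, adir: Path) -> None:
    cols: dict[str, np.ndarray] = {}
    for j in range(aligned.k):
        cols[f"x{j + 1}"] = aligned.coords[:, j, 0]
        cols[f"y{j + 1}"] = aligned.coords[:, j, 1]
    df = pd.DataFrame(cols, index=pd.Index(aligned.ids, name="id"))
    df["centroid_size"] = aligned.centroid_sizes
    df.to_csv(adir / "aligned_coords.csv")
    cons = io_formats.ShapeDataset(
        [io_formats.LandmarkConfiguration(id="consensus", points=aligned.consensus)]
    )
    io_formats.write_tps(cons, adir / "consensus.tps")
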