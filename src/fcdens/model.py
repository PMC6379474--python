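"""Study-level model: orchestrates the full connectivity-density analysis.

The entry point is :class:`FcdStudy`, a model object built from data
(simulated or loaded from NIfTI files plus a subject table) in the style of
statistical modelling packages: construct, then :meth:`FcdStudy.fit`, which
returns an :class:`FcdStudyResults` carrying the voxel-wise statistics,
cluster tables across the threshold sweep, ROC evaluation, clinical
correlations, and a ``summary()``.

Stages, in order: temporal preprocessing per subject; degree-map
computation at every connection threshold of the sweep; normalization and
smoothing; within-group one-sample maps with FDR; covariate-adjusted
two-sample GLM; Monte-Carlo cluster-extent correction; cluster extraction;
region-level ROC; Pearson correlations with clinical variables.  Everything
downstream of the random-number seed is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discrimination import (
    RegionValues,
    RocResult,
    combine_regions,
    extract_region_means,
    pearson_corr,
    roc,
    roc_table,
    summarize_roc_table,
)
from .fcd import FcdParams, compute_fcd, normalize_and_smooth
from .inference import (
    ClusterInferenceParams,
    ClusterResult,
    alphasim_min_extent,
    clusters_to_frame,
    estimate_smoothness,
    extract_clusters,
    fdr_threshold,
    min_extent_from_volume,
    one_sample_map,
    two_sample_glm,
)
from .preprocess import PreprocParams, run_preprocess
from .simulate import SimulationConfig, generate_dataset
from .volumes import BoldSeries, GrayMatterMask, load_bold, load_mask, save_volume

__all__ = ["FcdStudy", "FcdStudyResults", "dice"]

MAP_KINDS = ("short", "long")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


class FcdStudy:
    """Connectivity-density study model for a two-group BOLD dataset.

    Parameters
    ----------
    bold_list : list of BoldSeries
        One 4-D run per subject, all on the same grid as ``mask``.
    mask : GrayMatterMask
        Gray-matter analysis mask.
    subject_table : DataFrame
        Must contain ``subject_id``, ``group`` ("patient"/"control"), and
        the GLM covariates ``age`` and ``education``; any further numeric
        columns are treated as clinical variables for correlation.
    adopted_threshold : float
        The connection threshold whose group comparison feeds cluster
        extraction, ROC and correlations (0.45 by default); the remaining
        sweep thresholds serve the robustness analysis.
    """

    def __init__(
        self,
        bold_list: list[BoldSeries],
        mask: GrayMatterMask,
        subject_table: pd.DataFrame,
        preproc_params: PreprocParams | None = None,
        fcd_params: FcdParams | None = None,
        inference_params: ClusterInferenceParams | None = None,
        adopted_threshold: float = 0.45,
        fdr_q: float = 0.001,
        clinical_vars: list[str] | None = None,
        confounds: dict[str, pd.DataFrame] | None = None,
        hub_masks: list[np.ndarray] | None = None,
        seed: int = 0,
        config_dict: dict | None = None,
    ):
        if len(bold_list) < 4:
            raise ValueError("need at least 2 subjects per group")
        for b in bold_list:
            if b.grid.dims != mask.grid.dims:
                raise ValueError("all BOLD grids must match the mask grid")
        required = {"subject_id", "group", "age", "education"}
        missing = required - set(subject_table.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if len(subject_table) != len(bold_list):
            raise ValueError("subject table rows must match BOLD runs")
        groups = set(subject_table["group"])
        if groups != {"patient", "control"}:
            raise ValueError(f"group labels must be patient/control, got {groups}")

        self.bold_list = bold_list
        self.mask = mask
        self.table = subject_table.reset_index(drop=True)
        self.preproc_params = preproc_params or PreprocParams()
        self.fcd_params = fcd_params or FcdParams()
        self.inference_params = inference_params or ClusterInferenceParams()
        self.adopted_threshold = float(adopted_threshold)
        self.fdr_q = float(fdr_q)
        if clinical_vars is None:
            skip = {"subject_id", "group", "age", "education"}
            clinical_vars = [
                c for c in self.table.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.table[c])
            ]
        self.clinical_vars = clinical_vars
        self.confounds = confounds or {}
        self.hub_masks = hub_masks
        self.seed = int(seed)
        self.config_dict = config_dict

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_synthetic(cls, sim_config: SimulationConfig, **kwargs) -> "FcdStudy":
        """Simulate a dataset and wrap it as a study.

        The study seed defaults to the simulation seed.
        """
        from .simulate import default_mask

        bold_list, table, hub_masks = generate_dataset(sim_config)
        mask = default_mask(sim_config)
        kwargs.setdefault("seed", sim_config.seed)
        kwargs.setdefault("hub_masks", hub_masks)
        return cls(bold_list, mask, table, **kwargs)

    @classmethod
    def from_files(
        cls,
        bold_paths: list,
        mask_path,
        table_path,
        tr_s: float | None = None,
        **kwargs,
    ) -> "FcdStudy":
        """Build a study from NIfTI volumes and a CSV subject table.

        ``bold_paths`` order must match the subject table row order.
        """
        mask = load_mask(mask_path)
        table = pd.read_csv(table_path)
        bold_list = [
            load_bold(p, tr_s=tr_s, subject_id=str(sid))
            for p, sid in zip(bold_paths, table["subject_id"])
        ]
        return cls(bold_list, mask, table, **kwargs)

    @classmethod
    def from_config(cls, config: dict | str) -> "FcdStudy":
        """Build a study from a YAML file path or a config dictionary.

        The config carries exactly one data source (``data.synthetic`` with
        :class:`~fcdens.simulate.SimulationConfig` fields, or ``data.files``
        with ``bold``/``mask``/``table`` paths) plus optional ``preprocess``,
        ``fcd``, ``inference`` parameter blocks, ``adopted_threshold``,
        ``fdr_q``, ``clinical_vars`` and ``seed``.
        """
        from .config import load_config

        return load_config(config)

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #
    def fit(self, sweep: bool = True, verbose: bool = False) -> "FcdStudyResults":
        """Run the full analysis; returns a results object.

        With ``sweep=False`` only the adopted threshold is analyzed
        (faster; the robustness table is then empty).
        """
        log = (lambda msg: print(f"[fcdens] {msg}")) if verbose else (lambda msg: None)
        mask = self.mask
        coords = mask.world_coords()
        thresholds = (
            tuple(sorted(set(self.fcd_params.sweep_thresholds)
                         | {self.adopted_threshold}))
            if sweep
            else (self.adopted_threshold,)
        )
        if self.adopted_threshold not in thresholds:
            raise ValueError("adopted_threshold must be part of the sweep")

        log(f"preprocessing {len(self.bold_list)} subjects "
            f"({mask.n_voxels} mask voxels)")
        stacks: dict[float, dict[str, np.ndarray]] = {
            t: {k: np.empty((len(self.bold_list),) + mask.grid.dims)
                for k in MAP_KINDS}
            for t in thresholds
        }
        for i, bold in enumerate(self.bold_list):
            conf = self.confounds.get(bold.subject_id)
            mat = run_preprocess(bold, mask, self.preproc_params, conf)
            by_thr = compute_fcd(
                mat, coords, self.fcd_params, thresholds=thresholds, mask=mask
            )
            for t, maps in by_thr.items():
                final = normalize_and_smooth(maps, mask, self.fcd_params)
                for k in MAP_KINDS:
                    stacks[t][k][i] = final.map_of(k)
        log("degree maps computed; running group statistics")

        labels = self.table["group"].to_numpy()
        covars = self.table[["age", "education"]].to_numpy(dtype=float)
        is_patient = labels == "patient"

        # within-group one-sample maps at the adopted threshold
        one_sample: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for grp, sel in (("patient", is_patient), ("control", ~is_patient)):
            one_sample[grp] = {}
            for k in MAP_KINDS:
                t_map, p_map = one_sample_map(
                    stacks[self.adopted_threshold][k][sel], mask.membership
                )
                one_sample[grp][k] = {
                    "t": t_map,
                    "p": p_map,
                    "fdr_mask": fdr_threshold(p_map, self.fdr_q, mask.membership),
                }

        # two-sample GLM across the sweep
        glm: dict[float, dict[str, dict]] = {t: {} for t in thresholds}
        resid_for_fwhm = []
        for t in thresholds:
            for k in MAP_KINDS:
                t_map, df, resid = two_sample_glm(
                    stacks[t][k], labels, covars, return_residuals=True
                )
                glm[t][k] = {"t": t_map, "df": df}
                if t == self.adopted_threshold:
                    resid_for_fwhm.append(resid)

        # cluster-extent threshold: estimated smoothness + Monte-Carlo nulls
        inf = self.inference_params
        if inf.smoothness_fwhm_mm == "estimate":
            fwhm_axes = np.concatenate(
                [estimate_smoothness(r, mask) for r in resid_for_fwhm]
            )
            fwhm = float(np.nanmean(fwhm_axes))
        else:
            fwhm = float(inf.smoothness_fwhm_mm)
        log(f"residual smoothness {fwhm:.2f} mm FWHM")

        mc_null = None
        if inf.use_mc_extent:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 0xA15A]).generate_state(1)[0]
            )
            min_extent, mc_null = alphasim_min_extent(
                mask, fwhm, inf.voxel_p, inf.cluster_alpha,
                inf.n_mc_iterations, inf.connectivity, rng,
            )
        else:
            min_extent = min_extent_from_volume(
                inf.min_volume_mm3, mask.grid.voxel_size_mm
            )
        log(f"minimum cluster extent {min_extent} voxels")

        clusters: dict[float, dict[str, list[ClusterResult]]] = {}
        for t in thresholds:
            clusters[t] = {}
            for k in MAP_KINDS:
                clusters[t][k] = extract_clusters(
                    glm[t][k]["t"], glm[t][k]["df"], inf.voxel_p,
                    min_extent, inf.connectivity, mask.grid,
                )

        # region-level ROC + clinical correlations at the adopted threshold
        regions: list[RegionValues] = []
        roc_results: list[RocResult] = []
        for k in MAP_KINDS:
            for ci, cl in enumerate(clusters[self.adopted_threshold][k], start=1):
                rid = f"{k}_{cl.sign}_{ci}"
                rv = extract_region_means(
                    stacks[self.adopted_threshold][k], cl.member_voxels,
                    labels, region_id=rid,
                )
                regions.append(rv)
                roc_results.append(roc(rv))
        combined_roc = None
        if len(regions) >= 2:
            combined_roc = roc(combine_regions(regions))

        corr_rows = []
        pat = is_patient
        for rv in regions:
            for var in self.clinical_vars:
                y = self.table.loc[pat, var].to_numpy(dtype=float)
                x = rv.values[pat]
                if x.std() == 0 or y.std() == 0:
                    continue
                r, p = pearson_corr(x, y)
                corr_rows.append(
                    {"region": rv.region_id, "variable": var, "r": r, "p": p,
                     "n": int(pat.sum())}
                )
        correlations = pd.DataFrame(
            corr_rows, columns=["region", "variable", "r", "p", "n"]
        )

        provenance = {
            "package": "fcdens",
            "version": __version__,
            "seed": self.seed,
            "n_subjects": len(self.bold_list),
            "adopted_threshold": self.adopted_threshold,
            "thresholds": list(thresholds),
            "config_sha256": self._config_hash(),
        }
        log("done")
        return FcdStudyResults(
            model=self,
            thresholds=thresholds,
            stacks=stacks,
            one_sample=one_sample,
            glm=glm,
            clusters=clusters,
            min_extent_voxels=min_extent,
            smoothness_fwhm_mm=fwhm,
            mc_null_extents=mc_null,
            regions=regions,
            roc_results=roc_results,
            combined_roc=combined_roc,
            correlations=correlations,
            provenance=provenance,
        )

    def _config_hash(self) -> str:
        if self.config_dict is None:
            return ""
        blob = yaml.safe_dump(self.config_dict, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class FcdStudyResults:
    """Fitted study: statistics, clusters, ROC and correlation tables.

    Attributes of note
    ------------------
    clusters : {threshold: {"short"|"long": [ClusterResult]}}
        Corrected suprathreshold clusters of the patient-vs-control
        comparison at every sweep threshold.
    min_extent_voxels, smoothness_fwhm_mm
        The Monte-Carlo cluster-extent threshold and the residual
        smoothness it was simulated at.
    roc_results, combined_roc, correlations
        Region-level discrimination and clinical-correlation tables for
        the adopted threshold.
    """

    model: FcdStudy
    thresholds: tuple[float, ...]
    stacks: dict
    one_sample: dict
    glm: dict
    clusters: dict
    min_extent_voxels: int
    smoothness_fwhm_mm: float
    mc_null_extents: np.ndarray | None
    regions: list
    roc_results: list
    combined_roc: RocResult | None
    correlations: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    @property
    def adopted_threshold(self) -> float:
        return self.model.adopted_threshold

    def cluster_table(self) -> pd.DataFrame:
        """All corrected clusters across the sweep as one table."""
        frames = []
        for t in self.thresholds:
            for k in ("short", "long"):
                f = clusters_to_frame(self.clusters[t][k], map_kind=k)
                f.insert(0, "r_threshold", t)
                frames.append(f)
        # concatenating all-NA empty frames alongside filled ones is
        # deprecated in pandas; keep one empty frame only as the fallback
        filled = [f for f in frames if len(f)]
        return pd.concat(filled or frames[:1], ignore_index=True)

    def roc_frame(self) -> pd.DataFrame:
        results = list(self.roc_results)
        if self.combined_roc is not None:
            results = results + [self.combined_roc]
        return roc_table(results)

    def significant_mask(self, threshold: float, kind: str) -> np.ndarray:
        """Union of corrected cluster voxels at one threshold and map kind."""
        m = np.zeros(self.model.mask.grid.dims, dtype=bool)
        for cl in self.clusters[threshold][kind]:
            m[tuple(cl.member_voxels.T)] = True
        return m

    def threshold_robustness(self) -> pd.DataFrame:
        """Dice overlap of corrected-cluster masks against the adopted
        threshold, per map kind — the sweep concordance summary."""
        rows = []
        for k in ("short", "long"):
            ref = self.significant_mask(self.adopted_threshold, k)
            for t in self.thresholds:
                rows.append(
                    {
                        "map": k,
                        "r_threshold": t,
                        "dice_vs_adopted": dice(
                            self.significant_mask(t, k), ref
                        ),
                    }
                )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        """Human-readable overview of the fitted study."""
        m = self.model
        n_pat = int((m.table["group"] == "patient").sum())
        n_con = len(m.table) - n_pat
        lines = [
            "Functional connectivity density study",
            "=" * 54,
            f"subjects:            {n_pat} patients / {n_con} controls",
            f"mask voxels:         {m.mask.n_voxels}",
            f"connection sweep:    r = {', '.join(f'{t:g}' for t in self.thresholds)}",
            f"adopted threshold:   r = {self.adopted_threshold:g}",
            f"neighborhood radius: {m.fcd_params.radius_mm:g} mm "
            "(short <= radius < long)",
            f"residual smoothness: {self.smoothness_fwhm_mm:.2f} mm FWHM",
            f"cluster correction:  voxel p < {m.inference_params.voxel_p:g}, "
            f"alpha {m.inference_params.cluster_alpha:g}, "
            f"min extent {self.min_extent_voxels} voxels",
            "",
            "Corrected clusters (adopted threshold):",
        ]
        any_cluster = False
        for k in ("short", "long"):
            for cl in self.clusters[self.adopted_threshold][k]:
                any_cluster = True
                x, y, z = cl.peak_world_mm
                lines.append(
                    f"  {k:5s} {cl.sign:8s} extent {cl.extent_voxels:4d} vox "
                    f"({cl.extent_mm3:7.0f} mm3)  peak t {cl.peak_t:+7.3f} "
                    f"at ({x:.0f}, {y:.0f}, {z:.0f}) mm"
                )
        if not any_cluster:
            lines.append("  none")
        if self.roc_results:
            lines.append("")
            lines.append("Region discrimination (in-sample ROC):")
            for r in self.roc_results:
                lines.append(
                    f"  {r.region_id:20s} AUC {r.auc:.3f}  "
                    f"sens {100 * r.sensitivity:5.1f}%  "
                    f"spec {100 * r.specificity:5.1f}%  cutoff {r.cutoff:+.3f}"
                )
            if self.combined_roc is not None:
                r = self.combined_roc
                lines.append(
                    f"  {'combined':20s} AUC {r.auc:.3f}  "
                    f"sens {100 * r.sensitivity:5.1f}%  "
                    f"spec {100 * r.specificity:5.1f}%  cutoff {r.cutoff:+.3f}"
                )
        if len(self.correlations):
            sig = self.correlations[self.correlations["p"] < 0.05]
            lines.append("")
            lines.append(
                f"Clinical correlations (patients, p < 0.05): {len(sig)} of "
                f"{len(self.correlations)}"
            )
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row['region']:20s} ~ {row['variable']:18s} "
                    f"r = {row['r']:+.3f}  p = {row['p']:.4f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def save(self, outdir, write_maps: bool = True) -> None:
        """Write the report bundle: JSON summary, CSV tables, NIfTI maps."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cluster_table().to_csv(out / "clusters.csv", index=False)
        self.roc_frame().to_csv(out / "roc.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.threshold_robustness().to_csv(out / "robustness.csv", index=False)
        report = {
            "provenance": self.provenance,
            "min_extent_voxels": int(self.min_extent_voxels),
            "smoothness_fwhm_mm": float(self.smoothness_fwhm_mm),
            "n_clusters_adopted": {
                k: len(self.clusters[self.adopted_threshold][k])
                for k in ("short", "long")
            },
            "roc": self.roc_frame().to_dict(orient="records"),
            "roc_summary": (
                summarize_roc_table(self.roc_results) if self.roc_results else None
            ),
            "correlations": self.correlations.to_dict(orient="records"),
            "robustness": self.threshold_robustness().to_dict(orient="records"),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        if write_maps:
            grid = self.model.mask.grid
            t0 = self.adopted_threshold
            for k in ("short", "long"):
                save_volume(
                    out / f"tmap_{k}_r{t0:g}.nii.gz", self.glm[t0][k]["t"], grid
                )
                for grp in ("patient", "control"):
                    save_volume(
                        out / f"onesample_t_{grp}_{k}_r{t0:g}.nii.gz",
                        self.one_sample[grp][k]["t"],
                        grid,
                    )

    # ------------------------------------------------------------------ #
    def plot_roc(self, ax=None):
        """ROC curves for every region discriminator (and the combined
        score), drawn from the stored per-subject region values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        items = list(self.regions)
        if self.combined_roc is not None and len(self.regions) >= 2:
            items = items + [combine_regions(self.regions)]
        for rv in items:
            pos = rv.values[rv.labels == "patient"]
            neg = rv.values[rv.labels != "patient"]
            lo = min(rv.values.min(), 0) - 1
            hi = rv.values.max() + 1
            cuts = np.linspace(hi, lo, 101)
            if pos.mean() < neg.mean():
                pos, neg = -pos, -neg
                cuts = -cuts
            tpr = [(pos > c).mean() for c in cuts]
            fpr = [(neg > c).mean() for c in cuts]
            ax.plot(fpr, tpr, label=rv.region_id)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
        return ax

    def plot_map(self, kind: str = "short", z_slices=None, ax=None):
        """Axial montage of the adopted-threshold group-difference t map."""
        import matplotlib.pyplot as plt

        t_map = self.glm[self.adopted_threshold][kind]["t"]
        nz = t_map.shape[2]
        if z_slices is None:
            z_slices = range(0, nz, max(1, nz // 6))
        z_slices = list(z_slices)
        if ax is None:
            _, axes = plt.subplots(1, len(z_slices), figsize=(2 * len(z_slices), 2))
        else:
            axes = np.atleast_1d(ax)
        vmax = np.nanmax(np.abs(t_map)) or 1.0
        for a, z in zip(np.ravel(axes), z_slices):
            a.imshow(t_map[:, :, z].T, origin="lower", cmap="RdBu_r",
                     vmin=-vmax, vmax=vmax)
            a.set_title(f"z={z}", fontsize=7)
            a.axis("off")
        return axes
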