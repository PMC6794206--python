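"""Pipeline orchestration, bullseye tables/plots and group statistics.

``run_pipeline`` chains the full analysis — phantom generation or volume
loading, resampling, segmentation, frame construction, structure-tensor
orientation, angle maps and profiles, disarray index, wall thickness,
tractography — and writes a machine-readable results bundle (CSV tables,
NIfTI maps, VTK tracks and a JSON manifest) that is deterministic for a given
configuration and seed.

Group statistics follow standard practice for such studies: a Shapiro–Wilk
normality gate selects one-way ANOVA with Tukey's post-hoc test or the
Kruskal–Wallis test; full distributions are compared with the two-sample
Kolmogorov–Smirnov test. Significance is two-sided at 0.05.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .disarray import SegmentLayerSummary, mdi, mdi_wallthickness_correlation, summarize_mdi
from .geometry import (
    GRID45,
    SegmentModel,
    WallThicknessTable,
    assign_segments,
    build_frames,
    fit_axis,
    wall_thickness,
)
from .io import (
    ImageVolume,
    MyocardialMask,
    load_volume,
    resample_isotropic,
    save_mask,
    save_volume,
    segment_myocardium,
)
from .orientation import (
    angle_histograms,
    circumferential_fraction,
    helical_angle,
    intrusion_angle,
    ks_two_sample,
    structure_tensor,
    transmural_profiles,
    unwrap_helical,
)
from .phantom import PhantomSpec, make_vector_phantom, render_intensity
from .tracts import export_tracks, grid_seeds, track_fibers

log = logging.getLogger(__name__)

__all__ = [
    "BullseyeTable",
    "GroupComparison",
    "bullseye_table",
    "plot_bullseye",
    "run_pipeline",
    "compare_groups",
]

ALPHA = 0.05


@dataclass
class BullseyeTable:
    """Per-(level, sector) values for a polar segment plot."""

    scheme: str
    value_kind: str  # mdi | wall_thickness | mean_ha | mean_ia
    table: pd.DataFrame  # columns: level, sector, value

    def value(self, level: int, sector: int) -> float:
        row = self.table[(self.table.level == level) & (self.table.sector == sector)]
        return float(row.value.iloc[0]) if len(row) else float("nan")


@dataclass
class GroupComparison:
    """Between-group test result for one scalar metric."""

    metric: str
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    test: str  # anova_tukey | kruskal_wallis | descriptive
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None
    ks: pd.DataFrame | None = None


def bullseye_table(values: pd.DataFrame, value_kind: str, scheme: str = GRID45) -> BullseyeTable:
    """Build a bullseye table from a DataFrame with level/sector/value columns.

    Accepts segment summaries (``mean_mdi``), wall-thickness tables
    (``thickness_um`` with ``spoke`` as the sector) or any per-segment scalar.
    """
    df = values.copy()
    if "spoke" in df.columns:
        df = df.rename(columns={"spoke": "sector"})
    for cand in ("value", "mean_mdi", "thickness_um", "mean_ha", "mean_ia"):
        if cand in df.columns:
            df = df.rename(columns={cand: "value"})
            break
    else:
        raise ValueError("no value column found")
    out = df[["level", "sector", "value"]].sort_values(["level", "sector"]).reset_index(drop=True)
    return BullseyeTable(scheme, value_kind, out)


def plot_bullseye(bt: BullseyeTable, path, cmap: str = "viridis", title: str | None = None):
    """Render the bullseye as concentric rings (base outermost) of sector wedges."""
    levels = sorted(bt.table.level.unique())
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    vmin, vmax = bt.table.value.min(), bt.table.value.max()
    norm = plt.Normalize(vmin, vmax if vmax > vmin else vmin + 1)
    cm = plt.get_cmap(cmap)
    n_rings = len(levels)
    for ring, level in enumerate(levels):  # level 1 (base) outermost
        sub = bt.table[bt.table.level == level]
        r_out = 1.0 - ring / (n_rings + 1)
        r_in = 1.0 - (ring + 1) / (n_rings + 1)
        nsec = len(sub)
        for _, row in sub.iterrows():
            th0 = (row.sector - 1.5) * 2 * np.pi / nsec
            ax.bar(
                th0 + np.pi / nsec, r_out - r_in, width=2 * np.pi / nsec, bottom=r_in,
                color=cm(norm(row.value)), edgecolor="w", linewidth=0.5,
            )
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cm), ax=ax, label=bt.value_kind)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _float_df(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis described by a configuration mapping or JSON file.

    The configuration names either a ``phantom_spec`` (generated in memory) or
    an input ``volume`` (with ``spacing_um`` and ``landmarks`` for base/apex),
    plus optional stage parameters. Every stage's parameters are logged to
    ``manifest.json``; outputs are CSV/NIfTI/VTK files under ``out_dir``.
    Deterministic given the configuration and its seeds.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    config = dict(config)
    out_dir = Path(out_dir or config.get("out_dir", "myoarch_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    scheme = config.get("scheme", GRID45)
    stage = "input"
    try:
        gt = None
        if "phantom_spec" in config:
            spec_cfg = config["phantom_spec"]
            spec = spec_cfg if isinstance(spec_cfg, PhantomSpec) else PhantomSpec(**spec_cfg)
            gt = make_vector_phantom(spec)
            vol = render_intensity(gt)
            mask = gt.mask
            axis = gt.axis
            geometry = "cylindrical" if spec.geometry == "annulus" else "prolate"
            spec.to_json(out_dir / "phantom_spec.json")
        elif "volume" in config:
            vol = load_volume(config["volume"], config.get("spacing_um"))
            stage = "preprocess"
            vol = resample_isotropic(vol, config.get("target_um"))
            mask = segment_myocardium(vol, config.get("min_component_voxels", 64))
            if "landmarks" not in config:
                raise ValueError("non-phantom input requires base/apex 'landmarks'")
            axis = fit_axis(mask, landmarks=config["landmarks"])
            geometry = config.get("frame_geometry", "prolate")
        else:
            raise ValueError("config must provide 'phantom_spec' or 'volume'")

        stage = "geometry"
        frames = build_frames(mask, axis, geometry=geometry)
        segments = assign_segments(
            mask, axis, scheme, frames=frames, sector0_deg=config.get("sector0_deg", 0.0)
        )
        wt = wall_thickness(mask, axis, frames=frames)

        stage = "orientation"
        orient = structure_tensor(
            vol, mask,
            window_voxels=config.get("window_voxels", 3),
            gradient_sigma_um=config.get("gradient_sigma_um"),
        )
        ha_raw = helical_angle(orient, frames)
        ha = unwrap_helical(ha_raw, frames, mask)
        ia = intrusion_angle(orient, frames)
        profiles = transmural_profiles(ha, frames, segments)
        level_regions = {
            f"level{lv}": (segments.level_of == lv) for lv in range(1, segments.n_levels + 1)
        }
        circ = {
            name: circumferential_fraction(ha, region)
            for name, region in level_regions.items() if region.any()
        }
        hists = angle_histograms(ha, {k: v for k, v in level_regions.items() if v.any()})

        stage = "disarray"
        dmap = mdi(orient, mask, config.get("mdi_neighborhood", 9))
        summary = summarize_mdi(dmap, segments)
        corr = (
            mdi_wallthickness_correlation(summary, wt)
            if scheme == GRID45 and not summary.by_layer.empty else None
        )

        stage = "tracts"
        tracks = []
        if config.get("tracts", True):
            seeds = grid_seeds(mask, config.get("seed_every_voxels", 8))
            max_tracks = config.get("max_tracks", 200)
            if len(seeds) > max_tracks:
                keep = np.linspace(0, len(seeds) - 1, max_tracks).astype(int)
                seeds = seeds[keep]
            tracks = track_fibers(orient, mask, seeds)
            export_tracks(tracks, out_dir / "tracks.vtk", orient=orient, mask=mask)

        stage = "report"
        save_volume(ImageVolume(np.nan_to_num(ha, nan=-999), mask.spacing_um), out_dir / "ha.nii.gz")
        save_volume(ImageVolume(np.nan_to_num(ia, nan=-999), mask.spacing_um), out_dir / "ia.nii.gz")
        save_volume(ImageVolume(np.nan_to_num(dmap.mdi, nan=-1), mask.spacing_um), out_dir / "mdi.nii.gz")
        save_mask(mask, out_dir / "mask.nii.gz")
        _float_df(wt.table).to_csv(out_dir / "wall_thickness.csv", index=False)
        prof_df = pd.DataFrame(
            [
                (p.segment_id, p.level, p.sector, p.beta1, p.beta0, p.r2,
                 len(p.depth_samples), p.insufficient)
                for p in profiles
            ],
            columns=["segment", "level", "sector", "beta1", "beta0", "r2", "n_bins", "insufficient"],
        )
        _float_df(prof_df).to_csv(out_dir / "ha_profiles.csv", index=False)
        _float_df(summary.by_segment).to_csv(out_dir / "mdi_segments.csv", index=False)
        if not summary.by_layer.empty:
            _float_df(summary.by_layer).to_csv(out_dir / "mdi_layers.csv", index=False)
        if corr is not None:
            _float_df(corr).to_csv(out_dir / "mdi_wt_correlation.csv", index=False)
        pd.DataFrame(sorted(circ.items()), columns=["region", "circumferential_pct"]).round(
            6
        ).to_csv(out_dir / "circumferential_fraction.csv", index=False)
        bt_mdi = bullseye_table(summary.by_segment, "mdi", scheme)
        _float_df(bt_mdi.table).to_csv(out_dir / "bullseye_mdi.csv", index=False)
        plot_bullseye(bt_mdi, out_dir / "bullseye_mdi.png", title="mean MDI")
        bt_wt = bullseye_table(wt.table, "wall_thickness", scheme)
        _float_df(bt_wt.table).to_csv(out_dir / "bullseye_wall_thickness.csv", index=False)

        manifest = {
            "version": __version__,
            "scheme": scheme,
            "stages": {
                "input": {k: str(v) if isinstance(v, Path) else v
                          for k, v in config.items() if k not in ("phantom_spec",)},
                "geometry": {"frame_geometry": geometry, "focus_um": frames.focus_um,
                              "lv_length_um": axis.lv_length_um},
                "orientation": {"window_voxels": config.get("window_voxels", 3),
                                 "gradient_sigma_um": config.get("gradient_sigma_um")},
                "disarray": {"neighborhood_voxels": config.get("mdi_neighborhood", 9)},
                "tracts": {"n_tracks": len(tracks)},
            },
        }
        if "phantom_spec" in config:
            manifest["stages"]["input"]["phantom_spec"] = "phantom_spec.json"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except Exception as exc:  # pragma: no cover - error path formatting
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "out_dir": out_dir,
        "volume": vol,
        "mask": mask,
        "axis": axis,
        "frames": frames,
        "segments": segments,
        "orient": orient,
        "ha": ha,
        "ia": ia,
        "profiles": profiles,
        "mdi": dmap,
        "mdi_summary": summary,
        "wall_thickness": wt,
        "mdi_wt_correlation": corr,
        "circumferential_pct": circ,
        "histograms": hists,
        "tracks": tracks,
        "ground_truth": gt,
        "bullseye_mdi": bt_mdi,
    }


def compare_groups(samples: dict[str, np.ndarray], metric: str = "metric") -> GroupComparison:
    """Compare per-specimen scalar metrics between two or more groups.

    Each value in ``samples`` is the collection of per-specimen values of one
    group. A Shapiro–Wilk gate (all groups normal at the 0.05 level) selects
    one-way ANOVA with Tukey's post-hoc test; otherwise the Kruskal–Wallis
    test is used. Pairwise two-sample Kolmogorov–Smirnov results are reported
    alongside. Groups of size 1 yield descriptive statistics only.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    means = {k: float(a.mean()) for k, a in arrs.items()}
    sds = {k: float(a.std(ddof=1)) if len(a) > 1 else 0.0 for k, a in arrs.items()}
    if any(len(a) < 2 for a in arrs.values()):
        return GroupComparison(metric, labels, means, sds, "descriptive", np.nan, np.nan)

    normal = all(
        len(a) < 3 or stats.shapiro(a).pvalue > ALPHA for a in arrs.values()
    )
    posthoc = None
    if normal:
        res = stats.f_oneway(*arrs.values())
        test, statistic, p = "anova_tukey", float(res.statistic), float(res.pvalue)
        if len(labels) > 2:
            tk = stats.tukey_hsd(*arrs.values())
            rows = [
                (labels[i], labels[j], float(tk.statistic[i, j]), float(tk.pvalue[i, j]))
                for i in range(len(labels)) for j in range(len(labels)) if i < j
            ]
            posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p"])
    else:
        res = stats.kruskal(*arrs.values())
        test, statistic, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)

    ks_rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d, kp = ks_two_sample(arrs[labels[i]], arrs[labels[j]])
            ks_rows.append((labels[i], labels[j], d, kp))
    ks = pd.DataFrame(ks_rows, columns=["group_a", "group_b", "ks_stat", "ks_p"])
    return GroupComparison(metric, labels, means, sds, test, statistic, p, posthoc, ks)
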