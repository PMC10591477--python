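"""Whole-system analysis pipeline and two-system comparison reports.

``run_system`` executes every stage on one system (a topology plus its
independent-run trajectories): hinge-angle, A/B-helix-angle and
NcTnC-CcTnC-distance series, their distribution summaries, per-residue RMSF,
the residue-pair interaction frequency table, and the representative
(medoid) structure.  Outputs are diff-able CSV/JSON plus a run manifest
recording the configuration hash, cutoffs and stride.  ``compare_systems``
renders the metric-by-metric comparison table (mean/std, KDE mode, FWHM,
deltas, percent change, Cohen's d) and the interaction delta table for a
state pair such as unphosphorylated vs bisphosphorylated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluctuation, geometry, interactions, stats
from .structure_io import Topology, Trajectory, read_topology, read_trajectory, write_pdb_model

__all__ = ["AnalysisConfig", "run_system", "compare_systems", "load_config"]

METRICS = ("hinge", "ab_helix", "distance")


@dataclass
class AnalysisConfig:
    """One system's inputs and analysis settings."""

    topology: str
    trajectories: list[str]
    out_dir: str
    manifest: dict = field(default_factory=lambda: dict(geometry.DEFAULT_MANIFEST))
    cutoffs: interactions.InteractionCutoffs = field(
        default_factory=interactions.InteractionCutoffs
    )
    stats_config: stats.StatsConfig = field(default_factory=stats.StatsConfig)
    open_threshold: float = 110.0
    representative_max_frames: int = 200
    chain_map: dict | None = None

    def config_hash(self) -> str:
        """Hash of the analysis settings (not the input data paths)."""
        payload = json.dumps(
            {
                "manifest": self.manifest,
                "cutoffs": self.cutoffs.as_dict(),
                "open_threshold": self.open_threshold,
                "representative_max_frames": self.representative_max_frames,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from JSON."""
    raw = json.loads(Path(path).read_text())
    kwargs = dict(raw)
    if "cutoffs" in kwargs:
        kwargs["cutoffs"] = interactions.InteractionCutoffs(**kwargs["cutoffs"])
    if "stats_config" in kwargs:
        kwargs["stats_config"] = stats.StatsConfig(**kwargs["stats_config"])
    return AnalysisConfig(**kwargs)


def _series_frame(series: geometry.AngleSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": series.run_ids,
            "frame_index": series.frame_indices,
            "value": series.values,
        }
    )


def run_system(config: AnalysisConfig, trajectory: Trajectory | None = None) -> dict:
    """Run the full per-system analysis; returns the result bundle manifest.

    Stages run in a fixed order; any stage failure aborts with the stage
    name so partial outputs are identifiable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if trajectory is None:
            topology = read_topology(config.topology, config.chain_map)
            trajectory = read_trajectory(config.trajectories, topology)
        topology = trajectory.topology

        summaries: dict = {}
        for stage in METRICS:
            series = geometry.metric_series(trajectory, stage, config.manifest)
            _series_frame(series).to_csv(out / f"{stage}_series.csv", index=False)
            threshold = config.open_threshold if stage == "ab_helix" else None
            summary = stats.summarize(series.values, config.stats_config, threshold)
            summaries[stage] = summary.as_dict()
            summaries[stage]["n_failed_frames"] = series.n_failed

        stage = "rmsf"
        profile = fluctuation.rmsf(trajectory)
        pd.DataFrame(
            {
                "subunit": [k[0] for k in profile.residue_keys],
                "residue": [k[1] for k in profile.residue_keys],
                "rmsf": profile.values,
            }
        ).to_csv(out / "rmsf.csv", index=False)

        stage = "interactions"
        freq = interactions.profile_trajectory(trajectory, config.cutoffs)
        freq.table.to_csv(out / "interaction_frequencies.csv", index=False)

        stage = "representative"
        stride = max(1, int(np.ceil(trajectory.n_frames / config.representative_max_frames)))
        matrix = fluctuation.pairwise_rmsd_matrix(trajectory, "heavy", stride=stride)
        rep_label = fluctuation.representative_structure(matrix)
        global_idx = trajectory.frame_labels().index(rep_label)
        write_pdb_model(topology, trajectory.coordinates[global_idx], out / "representative.pdb")

        stage = "summary"
        bundle = {
            "config_hash": config.config_hash(),
            "n_frames": trajectory.n_frames,
            "n_runs": trajectory.n_runs,
            "cutoffs": config.cutoffs.as_dict(),
            "representative": {"run_id": rep_label[0], "frame_index": rep_label[1],
                               "stride": stride},
            "metrics": summaries,
        }
        (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


_METRIC_TITLES = {
    "hinge": "interdomain hinge angle",
    "ab_helix": "A/B helix angle",
    "distance": "NcTnC-CcTnC distance",
}


def compare_systems(bundle_a_dir: str | Path, bundle_b_dir: str | Path, out_dir: str | Path) -> dict:
    """Compare two result bundles (state B minus state A).

    Writes a comparison-table CSV (one row per metric: per-state mean/std,
    KDE mode, FWHM, deltas, FWHM change, Cohen's d) and the interaction
    delta-table CSV.  Both bundles must come from identical analysis
    configurations (hash check).
    """
    a_dir, b_dir = Path(bundle_a_dir), Path(bundle_b_dir)
    a = json.loads((a_dir / "summary.json").read_text())
    b = json.loads((b_dir / "summary.json").read_text())
    if a["config_hash"] != b["config_hash"]:
        raise ValueError("bundles were produced with different analysis configurations")

    rows = []
    comparisons: dict = {}
    for metric in METRICS:
        sa = _summary_from_dict(a["metrics"][metric])
        sb = _summary_from_dict(b["metrics"][metric])
        samples_a = pd.read_csv(a_dir / f"{metric}_series.csv").value.to_numpy()
        samples_b = pd.read_csv(b_dir / f"{metric}_series.csv").value.to_numpy()
        cmp = stats.state_delta(sa, sb, samples_a, samples_b)
        comparisons[metric] = cmp
        fmt = cmp.formatted()
        row = {
            "metric": _METRIC_TITLES[metric],
            "mean_a": round(sa.mean, 2),
            "std_a": round(sa.std, 2),
            "mean_b": round(sb.mean, 2),
            "std_b": round(sb.std, 2),
            "delta_mean": fmt["delta_mean"],
            "kde_a": round(sa.kde_mode, 2),
            "kde_b": round(sb.kde_mode, 2),
            "delta_kde": fmt["delta_kde_mode"],
            "fwhm_a": round(sa.fwhm, 2),
            "fwhm_b": round(sb.fwhm, 2),
            # angle metrics report FWHM percent change, distances absolute delta
            "delta_fwhm": fmt["delta_fwhm"] if metric == "distance" else None,
            "fwhm_percent_change": None if metric == "distance" else fmt.get("fwhm_percent_change"),
            "cohens_d": fmt.get("cohens_d"),
        }
        if metric == "ab_helix":
            row["fraction_above_a"] = sa.fraction_above
            row["fraction_above_b"] = sb.fraction_above
        rows.append(row)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = pd.DataFrame(rows)
    report.to_csv(out / "comparison_table.csv", index=False)

    ta = interactions.FrequencyTable(
        pd.read_csv(a_dir / "interaction_frequencies.csv"), a["n_frames"]
    )
    tb = interactions.FrequencyTable(
        pd.read_csv(b_dir / "interaction_frequencies.csv"), b["n_frames"]
    )
    delta = interactions.compare_states(ta, tb)
    delta.to_csv(out / "interaction_delta.csv", index=False)
    return {
        "comparison_table": str(out / "comparison_table.csv"),
        "interaction_delta": str(out / "interaction_delta.csv"),
        "comparisons": {m: c.formatted() for m, c in comparisons.items()},
    }


def _summary_from_dict(d: dict) -> stats.DistributionSummary:
    return stats.DistributionSummary(
        mean=d["mean"],
        std=d["std"],
        kde_mode=d["kde_mode"],
        fwhm=d["fwhm"] if d["fwhm"] is not None else float("nan"),
        n=d["n"],
        bandwidth=d["bandwidth"],
        fraction_above=d.get("fraction_above"),
        threshold=d.get("threshold"),
        degenerate=d.get("degenerate", False),
    )
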