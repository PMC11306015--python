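"""Evaluation protocol and attention interpretation.

Covers the accuracy metrics (R^2 relative to the 1:1 observed-vs-predicted
line, RMSE), the 5-fold genotype-stratified cross-validation protocol with
per-fold scores on both the independent test split and the complete dataset,
the four date-subset scenarios, aggregation of attention weights into
temporal importance profiles, and deterministic report rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SchemaError
from .genetics import FoldAssignment, stratified_folds
from .models import AttentionWeights, ModalityTensor, ModelConfig, RS_MODALITIES

__all__ = [
    "TemporalImportanceProfile",
    "ScenarioSpec",
    "EvaluationReport",
    "temporal_importance",
    "build_scenario",
    "apply_scenario",
    "r2_ref",
    "rmse",
    "cross_validate",
    "render_report",
]

#: default date-index subsets per scenario (0-based positions on a 7-date axis)
SCENARIO_DATE_INDICES = {
    1: {"lidar": None, "hyperspectral": None},          # all dates
    2: {"lidar": [0, 1, 2], "hyperspectral": [0, 1, 2]},  # up to mid-season
    3: {"lidar": [0, 1, 2, 3], "hyperspectral": [1, 2, 3, 5]},  # shifted
    4: {"lidar": [0, 1, 2], "hyperspectral": [0, 1, 2, 3]},
}


@dataclass
class TemporalImportanceProfile:
    """Mean attention mass per time-step (summed over features, over plots)."""

    values: np.ndarray
    dates: np.ndarray
    modality: str
    n_plots: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or abs(self.values.sum() - 1.0) > 1e-6:
            raise DomainError("temporal profile must be nonnegative and sum to 1")

    @property
    def argmax_date_index(self) -> int:
        return int(np.argmax(self.values))


@dataclass
class ScenarioSpec:
    """Retained date labels per modality for one prediction scenario."""

    scenario_id: int | str
    retained_dates: dict  # modality -> list of date labels

    def date_indices(self, tensor: ModalityTensor) -> np.ndarray:
        labels = list(np.asarray(tensor.dates).tolist())
        keep = self.retained_dates.get(tensor.modality)
        if keep is None:
            return np.arange(len(labels))
        missing = [d for d in keep if d not in labels]
        if missing:
            raise ConfigurationError(f"scenario dates {missing} absent from tensor")
        return np.array([labels.index(d) for d in keep], dtype=int)


@dataclass
class EvaluationReport:
    """Per-fold and aggregate scores in the two-column-pair layout
    (independent test data vs complete dataset)."""

    architecture: str
    scenario: int | str
    per_fold: pd.DataFrame
    aggregate: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.aggregate:
            metrics = ["r2_test", "rmse_test", "r2_complete", "rmse_complete"]
            self.aggregate = {
                m: {"mean": float(self.per_fold[m].mean()),
                    "sd": float(self.per_fold[m].std(ddof=1))}
                for m in metrics
            }


def temporal_importance(attention: AttentionWeights) -> TemporalImportanceProfile:
    """Sum weights over the feature axis, then average over plots."""
    w = attention.weights
    if w.shape[0] == 0:
        raise DomainError("no plots in attention weights")
    profile = w.sum(axis=2).mean(axis=0)
    return TemporalImportanceProfile(
        profile, attention.dates, attention.modality, w.shape[0]
    )


def build_scenario(
    scenario_id: int,
    date_labels,
    date_indices: dict | None = None,
) -> ScenarioSpec:
    """Date subsets of the four standard scenarios on the given date axis.

    Scenario 1 keeps every date in both modalities; Scenario 2 the earliest
    three; Scenario 3 four early LiDAR dates against four later-shifted
    hyperspectral dates; Scenario 4 three early/mid LiDAR dates and four
    hyperspectral dates.  `date_indices` overrides the positional defaults,
    e.g. to mirror a different year's calendar.
    """
    labels = list(np.asarray(date_labels).tolist())
    if date_indices is None:
        if scenario_id not in SCENARIO_DATE_INDICES:
            raise ConfigurationError(
                f"unknown scenario {scenario_id!r} without custom date indices"
            )
        date_indices = SCENARIO_DATE_INDICES[scenario_id]
    retained = {}
    for modality, idx in date_indices.items():
        if idx is None:
            retained[modality] = None
        else:
            if len(idx) == 0:
                raise ConfigurationError("a retained modality needs >= 1 date")
            if max(idx) >= len(labels):
                raise ConfigurationError("scenario date index beyond date axis")
            retained[modality] = [labels[i] for i in idx]
    return ScenarioSpec(scenario_id, retained)


def apply_scenario(tensors: dict, spec: ScenarioSpec) -> dict:
    """Subset each modality's date axis per the scenario.

    Weather is subset to the union of the dates retained across the
    remote-sensing modalities; feature values are untouched.
    """
    out = {}
    union = set()
    for m, t in tensors.items():
        if m == "weather":
            continue
        idx = spec.date_indices(t)
        if idx.size == 0:
            raise ConfigurationError(f"scenario retains no dates for {m}")
        out[m] = t.subset_dates(idx)
        union.update(np.asarray(out[m].dates).tolist())
    if "weather" in tensors:
        w = tensors["weather"]
        labels = list(np.asarray(w.dates).tolist())
        keep = [k for k, d in enumerate(labels) if d in union] or list(range(len(labels)))
        out["weather"] = w.subset_dates(np.array(keep, dtype=int))
    return out


def r2_ref(y_obs, y_pred, printed_form: bool = False) -> float:
    """Coefficient of determination against the 1:1 reference line.

    Returns 1 - SSres/SStot (larger is better).  ``printed_form=True`` gives
    the bare ratio SSres/SStot instead.
    """
    y = np.asarray(y_obs, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size != p.size:
        raise SchemaError("y_obs and y_pred lengths differ")
    if y.size < 2:
        raise DomainError("r2_ref needs >= 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("zero variance in observed values: score undefined")
    ratio = float(np.sum((y - p) ** 2)) / ss_tot
    return ratio if printed_form else 1.0 - ratio


def rmse(y_obs, y_pred) -> float:
    """Root mean squared error, sqrt(sum((y_hat - y)^2)/n)."""
    y = np.asarray(y_obs, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size != p.size:
        raise SchemaError("y_obs and y_pred lengths differ")
    if y.size < 1:
        raise SchemaError("rmse needs >= 1 sample")
    return float(np.sqrt(np.mean((p - y) ** 2)))


def cross_validate(
    y: np.ndarray,
    tensors: dict,
    model_cls,
    config: ModelConfig | None = None,
    folds: FoldAssignment | None = None,
    plot_table: pd.DataFrame | None = None,
    scenario: ScenarioSpec | int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """k-fold protocol: fit per fold, score the independent test split and
    the complete dataset, aggregate mean +/- sd across folds.

    Either a :class:`FoldAssignment` or a plot table with cluster labels
    (from which stratified folds are built) must be supplied.  Checks are
    expected to be excluded upstream.
    """
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        if plot_table is None:
            raise ConfigurationError("need folds or a plot table with clusters")
        folds = stratified_folds(plot_table, seed=seed)
    if isinstance(scenario, int):
        any_rs = tensors[RS_MODALITIES[0]]
        scenario = build_scenario(scenario, any_rs.dates)
    sub = apply_scenario(tensors, scenario)

    pos_of = {pid: k for k, pid in enumerate(
        folds.table.loc[folds.table["fold"] == 0, "plot_id"].to_numpy()
    )}
    rows = []
    for fold in range(folds.n_folds):
        tr = np.array([pos_of[p] for p in folds.ids(fold, "train")])
        va = np.array([pos_of[p] for p in folds.ids(fold, "validation")])
        te = np.array([pos_of[p] for p in folds.ids(fold, "test")])
        if te.size == 0:
            raise ConfigurationError(f"fold {fold} has an empty test split")
        cfg = config if config is not None else ModelConfig()
        model = model_cls(y, sub, cfg)
        res = model.fit(tr, va)
        pred_all = res.predict()
        rows.append(
            {
                "fold": fold,
                "r2_test": r2_ref(y[te], pred_all[te]),
                "rmse_test": rmse(y[te], pred_all[te]),
                "r2_complete": r2_ref(y, pred_all),
                "rmse_complete": rmse(y, pred_all),
                "n_test": int(te.size),
            }
        )
    per_fold = pd.DataFrame(rows)
    return EvaluationReport(
        architecture=model_cls.arch, scenario=scenario.scenario_id, per_fold=per_fold
    )


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.2f} ± {sd:.2f}"


def render_report(
    reports: list[EvaluationReport],
    profiles: list[TemporalImportanceProfile] | None = None,
    out_dir=None,
    make_figures: bool = False,
) -> dict:
    """Deterministic table-style CSV/JSON outputs plus optional figures.

    The summary table mirrors the mean +/- sd layout with column pairs for
    the independent test data and the complete dataset.
    """
    summary_rows = []
    payload = {"reports": [], "profiles": []}
    for rep in reports:
        agg = rep.aggregate
        summary_rows.append(
            {
                "scenario": rep.scenario,
                "architecture": rep.architecture,
                "r2_test": _fmt(**agg["r2_test"]),
                "rmse_test": _fmt(**agg["rmse_test"]),
                "r2_complete": _fmt(**agg["r2_complete"]),
                "rmse_complete": _fmt(**agg["rmse_complete"]),
            }
        )
        payload["reports"].append(
            {
                "scenario": rep.scenario,
                "architecture": rep.architecture,
                "aggregate": agg,
                "per_fold": rep.per_fold.round(10).to_dict(orient="records"),
            }
        )
    summary = pd.DataFrame(summary_rows)
    profiles = profiles or []
    profile_rows = []
    for prof in profiles:
        for d, v in zip(np.asarray(prof.dates).tolist(), prof.values):
            profile_rows.append(
                {"modality": prof.modality, "date": d, "importance": round(float(v), 10)}
            )
        payload["profiles"].append(
            {"modality": prof.modality, "dates": np.asarray(prof.dates).tolist(),
             "values": [round(float(v), 10) for v in prof.values]}
        )
    outputs = {"summary": summary, "profiles": pd.DataFrame(profile_rows)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "metrics_summary.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        if profile_rows:
            outputs["profiles"].to_csv(out / "temporal_importance.csv", index=False)
        if make_figures and profiles:
            _plot_figures(profiles, out)
    return outputs


def _plot_figures(profiles, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        ax.plot(range(len(prof.values)), prof.values, marker="o", label=prof.modality)
    ax.set_xlabel("acquisition date index")
    ax.set_ylabel("mean attention mass")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "temporal_importance.png", dpi=120)
    plt.close(fig)
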