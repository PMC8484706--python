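"""Flow-field error functionals and region-wise evaluation.

Two complementary errors compare a predicted field Q-hat with the reference
field Q over the N2 query points of one model:

* **NMAE** (normalized mean absolute error, %) — mean |Q_i - Q-hat_i|
  normalized by the per-model magnitude range Max|Q| - Min|Q|; a whole-model
  summary insensitive to the field's absolute scale;
* **MRE** (mean relative error, %) — mean per-point |Q_i - Q-hat_i| / |Q_i|;
  a pointwise accuracy measure.  Points with |Q_i| below a floor (default
  1e-3 of the per-model max magnitude) are excluded — the ratio is unbounded
  at near-wall points where the true value vanishes — and the exclusion
  count is always reported.

Velocity fields are scalarized to their magnitude |V| before either error
(per-component mode available).  Evaluation is reported for the whole model
and for the aneurysm-sac region separately, aggregated as mean ± std across
test models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import REGION_SAC

__all__ = ["nmae", "mre", "evaluate", "ErrorReport"]


class DegenerateFieldError(ValueError):
    """Raised when a field has no usable range for the requested metric."""


def _check(truth, pred) -> Tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if truth.shape != pred.shape or truth.size == 0:
        raise ValueError("truth and pred must be equally sized and non-empty")
    return truth, pred


def nmae(truth, pred, norm_range: Optional[float] = None) -> float:
    """Normalized mean absolute error, percent.

    ``100 * mean|Q - Q_hat| / (Max|Q| - Min|Q|)``.  The magnitude range is
    taken over the values passed in unless ``norm_range`` is given — region
    evaluation passes the whole-model range, since the normalization is
    defined per model, not per evaluated subset.
    """
    truth, pred = _check(truth, pred)
    if norm_range is None:
        mag = np.abs(truth)
        norm_range = float(mag.max() - mag.min())
    if norm_range <= 0.0:
        raise DegenerateFieldError("zero magnitude range: NMAE undefined")
    return float(100.0 * np.mean(np.abs(truth - pred)) / norm_range)


def mre(truth, pred, floor: Optional[float] = None, return_excluded: bool = False):
    """Mean relative error, percent: ``100 * mean sqrt((Q - Q_hat)^2 / Q^2)``.

    Points with ``|Q| < floor`` are excluded (floor defaults to
    ``1e-3 * max|Q|``); set ``return_excluded`` to also get their count.
    """
    truth, pred = _check(truth, pred)
    if floor is None:
        floor = 1e-3 * np.abs(truth).max()
    # exact zeros are always excluded: the per-point ratio is undefined there
    keep = (np.abs(truth) >= floor) & (truth != 0.0)
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise DegenerateFieldError("all points below the relative-error floor")
    # sqrt((Q - Q_hat)^2 / Q^2) == |Q - Q_hat| / |Q|, computed without the
    # intermediate squares (which underflow for tiny magnitudes)
    val = float(100.0 * np.mean(np.abs((truth[keep] - pred[keep]) / truth[keep])))
    return (val, n_excluded) if return_excluded else val


@dataclass
class ErrorReport:
    """Per-model and aggregated NMAE/MRE for whole-model and sac regions.

    ``per_model[region][metric]`` is one value per test model;
    ``summary[region][metric]`` is (mean, std) across models.
    """

    variant: Tuple[str, str]
    per_model: Dict[str, Dict[str, List[float]]] = field(default_factory=dict)
    excluded: Dict[str, List[int]] = field(default_factory=dict)
    n_models: int = 0

    REGIONS = ("whole", "aneurysm")
    METRICS = ("nmae", "mre")

    @property
    def summary(self) -> Dict[str, Dict[str, Tuple[float, float]]]:
        out: Dict[str, Dict[str, Tuple[float, float]]] = {}
        for region, metrics in self.per_model.items():
            out[region] = {}
            for metric, values in metrics.items():
                arr = np.asarray(values, dtype=float)
                out[region][metric] = (float(arr.mean()), float(arr.std(ddof=0)))
        return out

    def max_value(self, metric: str) -> float:
        """Worst per-model value of ``metric`` across regions."""
        return max(max(vals) for region, metrics in self.per_model.items()
                   for name, vals in metrics.items() if name == metric)

    def to_dict(self) -> Dict:
        return {"variant": list(self.variant), "n_models": self.n_models,
                "per_model": self.per_model, "excluded": self.excluded,
                "summary": {r: {m: list(v) for m, v in d.items()}
                            for r, d in self.summary.items()}}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def format_table(self) -> str:
        """Human-readable summary table (mean ± std across test models, %)."""
        state, quantity = self.variant
        lines = [f"Variant: {state} / {quantity}   (n = {self.n_models} test models)",
                 f"{'Part':<12} {'NMAE [%]':>16} {'MRE [%]':>16}"]
        s = self.summary
        for region, label in (("whole", "Whole model"), ("aneurysm", "Aneurysm")):
            if region not in s:
                continue
            nm = s[region]["nmae"]
            mr = s[region]["mre"]
            lines.append(f"{label:<12} {nm[0]:7.2f} ± {nm[1]:5.2f}  "
                         f"{mr[0]:7.2f} ± {mr[1]:5.2f}")
        return "\n".join(lines)


def evaluate(model, test_set, per_component: bool = False,
             floor: Optional[float] = None) -> ErrorReport:
    """Predict on every test pair and build the region-wise error report.

    ``model`` is a fitted estimator; ``test_set`` a ``HemoDataset`` whose
    variant matches the model's output dimension.  Velocity targets are
    scalarized to |V| unless ``per_component``; the sac region uses the
    query-cloud region labels.
    """
    quantity = test_set.variant[1]
    expected_dim = 3 if quantity == "velocity" else 1
    if getattr(model, "output_dim", expected_dim) != expected_dim:
        raise ValueError(
            f"model output_dim {model.output_dim} incompatible with {quantity} data")
    report = ErrorReport(variant=test_set.variant)
    report.per_model = {r: {m: [] for m in ErrorReport.METRICS}
                        for r in ErrorReport.REGIONS}
    report.excluded = {r: [] for r in ErrorReport.REGIONS}
    X, y = test_set.to_xy()
    preds = model.predict(X)
    for pair, truth, pred in zip(test_set.pairs, y, preds):
        if pair.query_cloud.region is None:
            raise ValueError("query cloud lacks region labels")
        if quantity == "velocity" and not per_component:
            truth_s = np.linalg.norm(truth, axis=1)
            pred_s = np.linalg.norm(pred, axis=1)
        else:
            truth_s = truth.ravel()
            pred_s = np.asarray(pred).reshape(truth.shape).ravel()
        sac = pair.query_cloud.region == REGION_SAC
        masks = {"whole": np.ones(truth_s.shape, bool),
                 "aneurysm": np.repeat(sac, truth.shape[1]) if per_component else sac}
        # per-model normalization: Max|Q|, Min|Q| and the MRE floor refer to
        # the whole model's values even when a sub-region is evaluated
        mag = np.abs(truth_s)
        model_range = float(mag.max() - mag.min())
        model_floor = floor if floor is not None else 1e-3 * float(mag.max())
        for region, mask in masks.items():
            if not np.any(mask):
                continue
            t_r, p_r = truth_s[mask], pred_s[mask]
            report.per_model[region]["nmae"].append(nmae(t_r, p_r, norm_range=model_range))
            val, nex = mre(t_r, p_r, floor=model_floor, return_excluded=True)
            report.per_model[region]["mre"].append(val)
            report.excluded[region].append(nex)
    report.n_models = len(test_set.pairs)
    return report
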