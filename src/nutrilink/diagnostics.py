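"""Goodness of fit of the bivariate model via the correct classification rate.

For a pair of binary outcomes the CCR is the (weighted) share of
observations whose predicted outcome category equals the observed one.  Two
classification rules are available:

* ``argmax_joint`` (default) — the predicted joint category is the argmax of
  the four fitted cell probabilities; the natural rule for a joint model.
* ``marginal_threshold`` — each margin is predicted by pi_j >= 0.5 and the
  joint prediction is the pair; under this rule the joint CCR can never
  exceed either marginal CCR.

Marginal CCRs are reported under both rules.  Argmax ties (a measure-zero
event) are broken deterministically in the fixed cell order
(p00, p10, p01, p11).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bivlogit import BivariateFit, DesignMatrix, predict_joint

__all__ = ["CCRResult", "correct_classification_rate"]

# order used for tie-breaking and for the confusion matrix axes
_CELL_ORDER = [(0, 0), (1, 0), (0, 1), (1, 1)]


@dataclass
class CCRResult:
    joint_ccr: float
    marginal_ccr_anemia: float
    marginal_ccr_undernutrition: float
    rule: str
    confusion: np.ndarray  # 4x4 weighted counts, rows observed, cols predicted

    def to_dict(self) -> dict:
        return {
            "joint_ccr": self.joint_ccr,
            "marginal_ccr_anemia": self.marginal_ccr_anemia,
            "marginal_ccr_undernutrition": self.marginal_ccr_undernutrition,
            "rule": self.rule,
            "cell_order": [list(c) for c in _CELL_ORDER],
            "confusion": self.confusion.tolist(),
        }


def correct_classification_rate(
    fit_result: BivariateFit,
    design: DesignMatrix,
    y,
    rule: str = "argmax_joint",
    psi_design=None,
) -> CCRResult:
    """Weighted CCR of the fitted bivariate model under the chosen rule."""
    if rule not in ("argmax_joint", "marginal_threshold"):
        raise ValueError(f"unknown classification rule: {rule!r}")
    cells = predict_joint(fit_result, design, psi_design=psi_design)
    # reorder from (p11, p10, p01, p00) to the tie-break order
    reordered = cells[:, [3, 1, 2, 0]]  # p00, p10, p01, p11

    arr = np.asarray(y, dtype=float) if not hasattr(y, "to_numpy") else y.to_numpy()
    arr = np.asarray(arr, dtype=float)
    y1 = arr[:, 0].astype(int)
    y2 = arr[:, 1].astype(int)
    w = design.weights
    wsum = w.sum()

    if rule == "argmax_joint":
        pred_cell = np.argmax(reordered, axis=1)  # first max wins the tie
        pred = np.array(_CELL_ORDER)[pred_cell]
        pred1, pred2 = pred[:, 0], pred[:, 1]
    else:
        pi1 = cells[:, 0] + cells[:, 1]  # p11 + p10
        pi2 = cells[:, 0] + cells[:, 2]  # p11 + p01
        pred1 = (pi1 >= 0.5).astype(int)
        pred2 = (pi2 >= 0.5).astype(int)

    joint_correct = (pred1 == y1) & (pred2 == y2)
    obs_idx = np.array([_CELL_ORDER.index((a, b)) for a, b in zip(y1, y2)])
    pred_idx = np.array([_CELL_ORDER.index((a, b)) for a, b in zip(pred1, pred2)])
    confusion = np.zeros((4, 4))
    np.add.at(confusion, (obs_idx, pred_idx), w)

    return CCRResult(
        joint_ccr=float(np.sum(w * joint_correct) / wsum),
        marginal_ccr_anemia=float(np.sum(w * (pred1 == y1)) / wsum),
        marginal_ccr_undernutrition=float(np.sum(w * (pred2 == y2)) / wsum),
        rule=rule,
        confusion=confusion,
    )
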