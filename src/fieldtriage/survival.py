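"""Chance-of-survival function: a two-stage RBF-SVM over the triage grid.

The triage cascade yields an ordinal label (green / yellow / red).  The
chance-of-survival function refines it into a percentage so that casualties
carrying the same color can still be ranked: the red class spans 1–50 %,
yellow 51–99 % and green is exactly 100 %.

Training data is a Cartesian grid over the four-dimensional vital-sign
space (RR x HR x SBP x SpO2), labeled by the triage engine itself; the
default axis resolutions 10 x 12 x 12 x 5 give 7200 cases spanning from
below-critical to within-reference on every axis.  Two nonlinear
support-vector machines are composed ordinally:

* stage A separates red from {yellow, green};
* stage B separates yellow from green among the not-red cases.

A percentage is obtained by logistic squashing of the signed margin
distance of the deciding stage, affinely mapped into the predicted class
band and clamped; green is forced to exactly 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from fieldtriage.triage import (
    ReferenceProfile,
    Sign,
    SignRange,
    TriageColor,
    VitalSnapshot,
    triage,
)

__all__ = [
    "AxisSpec",
    "CaseGrid",
    "SurvivalModel",
    "DEFAULT_AXES",
    "BANDS",
    "generate_case_grid",
    "label_grid",
    "train_survival_model",
    "survival_chance",
    "band_compliance",
    "TrainingError",
]

#: Output bands per color, in percent.
BANDS: Mapping[TriageColor, tuple[int, int]] = {
    TriageColor.RED: (1, 50),
    TriageColor.YELLOW: (51, 99),
    TriageColor.GREEN: (100, 100),
}


@dataclass(frozen=True)
class AxisSpec:
    """Strictly increasing grid values for one vital sign."""

    sign: Sign
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"axis {self.sign} needs at least 2 values")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(
                f"axis {self.sign} values must be strictly increasing "
                "(duplicates not allowed)"
            )


# Default axes span from below the critical threshold up to (and through)
# the reference interval on every sign; SpO2 gets the fewest levels since
# its scale is one-sided.  Levels sit on a uniform ladder of the normalised
# band deviation z (0 = centre of the reference interval, |z| = 1 at the
# reference bounds, |z| = 2 at the critical thresholds), with each pair of
# levels straddling a clinical threshold placed symmetrically around it, so
# the boundary a margin classifier learns between them falls on the
# threshold itself.  10 * 12 * 12 * 5 = 7200 cases.
DEFAULT_AXES: tuple[AxisSpec, ...] = (
    AxisSpec(Sign.RR, (2.6, 4.2, 5.8, 8.2, 10.1, 14.5, 18.9, 22.0, 28.0, 32.0)),
    AxisSpec(
        Sign.HR,
        (32.5, 37.5, 42.5, 47.5, 57.5, 72.5, 87.5, 102.5, 117.5, 132.5, 147.5, 162.5),
    ),
    AxisSpec(
        Sign.SBP,
        (65.0, 75.0, 85.0, 95.0, 110.0, 130.0, 150.0, 170.0, 190.0, 210.0, 230.0, 250.0),
    ),
    AxisSpec(Sign.SPO2, (82.75, 87.25, 91.75, 94.75, 97.75)),
)


@dataclass
class CaseGrid:
    """Cartesian product of per-sign axis values.

    ``cases`` is an (n, 4) array in sign order RR, HR, SBP, SpO2.
    """

    axes: tuple[AxisSpec, ...]
    cases: np.ndarray
    grid_id: str = "default"

    def __len__(self) -> int:
        return self.cases.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cases, columns=["rr", "hr", "sbp", "spo2"])

    def export_csv(
        self, path: str | Path, labels: Sequence[TriageColor] | None = None
    ) -> None:
        df = self.to_frame()
        if labels is not None:
            df["color"] = [c.value for c in labels]
        df.to_csv(path, index=False)


def generate_case_grid(
    axes: Sequence[AxisSpec] = DEFAULT_AXES, grid_id: str = "default"
) -> CaseGrid:
    """Build the full factorial grid of vital-sign cases.

    The case count is the product of the axis lengths; the default axes
    give 7200.  Generation is deterministic given the axis specification.
    """
    axes = tuple(axes)
    if tuple(a.sign for a in axes) != (Sign.RR, Sign.HR, Sign.SBP, Sign.SPO2):
        raise ValueError("axes must be given in order RR, HR, SBP, SpO2")
    mesh = np.meshgrid(*(np.asarray(a.values, float) for a in axes), indexing="ij")
    cases = np.stack([m.ravel() for m in mesh], axis=1)
    return CaseGrid(axes=axes, cases=cases, grid_id=grid_id)


def label_grid(grid: CaseGrid, profile: ReferenceProfile) -> list[TriageColor]:
    """Label every grid case with the triage cascade (the oracle labels)."""
    labels = []
    for rr, hr, sbp, spo2 in grid.cases:
        snap = VitalSnapshot(
            soldier_id=profile.soldier_id,
            timestamp=0,
            rr=rr,
            hr=hr,
            sbp=sbp,
            spo2=spo2,
        )
        labels.append(triage(snap, profile).color)
    return labels


@dataclass
class RbfStage:
    """A fitted binary RBF machine reduced to its kernel expansion.

    The decision value is ``sum_i alpha_i * exp(-gamma * ||x - sv_i||^2)
    + b``; positive values point toward the "better" class (not-red for
    stage A, green for stage B).  Keeping only the expansion makes the model
    serialisable as plain JSON.
    """

    support_vectors: np.ndarray  # (m, 4), standardised feature space
    dual_coef: np.ndarray  # (m,)
    intercept: float
    gamma: float

    @classmethod
    def from_svc(cls, svc: SVC) -> "RbfStage":
        return cls(
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_.ravel().copy(),
            intercept=float(svc.intercept_[0]),
            gamma=float(svc._gamma),
        )

    def decision_function(self, Xs: np.ndarray) -> np.ndarray:
        sq = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Xs @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfStage":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
        )


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


#: Relative weight of the band-deviation excess in the calibration score;
#: heavy enough that its monotone gradient dominates kernel ripple in the
#: far field, light enough that the margin shapes the score near the
#: boundary.
_DEV_WEIGHT = 2.0


def band_deviation(X: np.ndarray, ranges: "dict[Sign, SignRange]") -> np.ndarray:
    """Normalised deviation of each vital from its reference band.

    z = 0 at the centre of the reference interval, |z| = 1 at the
    reference bounds and |z| = 2 at the critical thresholds (piecewise
    linear in between and beyond).  This is the feature space the survival
    classifiers operate in: it puts all four signs on one clinical scale
    and makes the color regions concentric boxes (green |z| <= 1,
    critical |z| >= 2).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.empty_like(X)
    for j, sign in enumerate(Sign):
        r = ranges[sign]
        v = X[:, j]
        mid = 0.5 * (r.ref_lo + r.ref_hi)
        half = 0.5 * (r.ref_hi - r.ref_lo)
        z = (v - mid) / half
        if r.crit_lo is not None:
            z = np.where(
                v < r.ref_lo, -1.0 - (r.ref_lo - v) / (r.ref_lo - r.crit_lo), z
            )
        if r.crit_hi is not None:
            z = np.where(
                v > r.ref_hi, 1.0 + (v - r.ref_hi) / (r.crit_hi - r.ref_hi), z
            )
        Z[:, j] = z
    return Z


@dataclass
class SurvivalModel:
    """Two-stage large-margin classifier with band calibration.

    ``stage_a`` votes red vs not-red, ``stage_b`` yellow vs green.  The
    calibration squashes the deciding stage's signed margin through a
    logistic (scaled by the median training margin so it stays responsive
    across the training cloud), stretches it into the band of the predicted
    class and clamps; green maps to exactly 100.
    """

    ranges: "dict[Sign, SignRange]"
    stage_a: RbfStage
    stage_b: RbfStage
    margin_scales: tuple[float, float]
    seed: int
    bands: Mapping[TriageColor, tuple[int, int]] = field(
        default_factory=lambda: dict(BANDS)
    )

    def decision_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = band_deviation(X, self.ranges)
        return self.stage_a.decision_function(Z), self.stage_b.decision_function(Z)

    def predict_color(self, X: np.ndarray) -> list[TriageColor]:
        d_a, d_b = self.decision_values(X)
        out = []
        for da, db in zip(d_a, d_b):
            if da <= 0:
                out.append(TriageColor.RED)
            elif db <= 0:
                out.append(TriageColor.YELLOW)
            else:
                out.append(TriageColor.GREEN)
        return out

    def chance(self, X: np.ndarray) -> np.ndarray:
        """Calibrated survival percentages (integers) for cases X (n, 4).

        The class comes from the two machines; the within-band percentage
        squashes a calibration score through a logistic.  The score blends
        the deciding stage's margin with the case's excess band deviation
        beyond the class edge (|z| = 2 for red, 1 for yellow): the RBF
        margin saturates far outside the training cloud and drifts back
        toward its intercept, while the deviation term keeps the ranking
        monotone as vitals keep worsening.
        """
        d_a, d_b = self.decision_values(X)
        Z = band_deviation(np.atleast_2d(np.asarray(X, float)), self.ranges)
        max_dev = np.max(np.abs(Z), axis=1)
        s_a, s_b = self.margin_scales
        out = np.empty(d_a.shape[0])
        for i, (da, db) in enumerate(zip(d_a, d_b)):
            if da <= 0:  # red side
                lo, hi = self.bands[TriageColor.RED]
                score = da / s_a + _DEV_WEIGHT * (2.0 - max_dev[i])
                val = lo + _logistic(score) * 2.0 * (hi - lo)
            elif db <= 0:  # yellow
                lo, hi = self.bands[TriageColor.YELLOW]
                score = db / s_b + _DEV_WEIGHT * (1.0 - max_dev[i])
                val = lo + _logistic(score) * 2.0 * (hi - lo)
            else:  # green
                out[i] = 100.0
                continue
            out[i] = min(max(val, lo), hi)
        return np.rint(out).astype(int)

    # -- persistence (versioned JSON, binary-free) ------------------------
    def save(self, path: str | Path) -> None:
        doc = {
            "format": "fieldtriage-survival-model",
            "version": 1,
            "seed": self.seed,
            "margin_scales": list(self.margin_scales),
            "bands": {c.value: list(b) for c, b in self.bands.items()},
            "ranges": {
                sign.value: [r.ref_lo, r.ref_hi, r.crit_lo, r.crit_hi]
                for sign, r in self.ranges.items()
            },
            "stage_a": self.stage_a.to_dict(),
            "stage_b": self.stage_b.to_dict(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "SurvivalModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fieldtriage-survival-model":
            raise ValueError("not a survival-model file")
        return cls(
            ranges={
                Sign(k): SignRange(ref_lo=v[0], ref_hi=v[1], crit_lo=v[2], crit_hi=v[3])
                for k, v in doc["ranges"].items()
            },
            stage_a=RbfStage.from_dict(doc["stage_a"]),
            stage_b=RbfStage.from_dict(doc["stage_b"]),
            margin_scales=tuple(doc["margin_scales"]),
            seed=int(doc["seed"]),
            bands={TriageColor(c): tuple(b) for c, b in doc["bands"].items()},
        )


class TrainingError(ValueError):
    """Degenerate training labels (a class is missing)."""


def train_survival_model(
    grid: CaseGrid,
    labels: Sequence[TriageColor],
    seed: int,
    C: float = 500.0,
    gamma: float = 3.0,
    profile: ReferenceProfile | None = None,
) -> SurvivalModel:
    """Fit the two-stage classifier to a triage-labeled case grid.

    Requires all three colors among the labels.  Cases are mapped to
    normalised band-deviation features (see :func:`band_deviation`) against
    ``profile`` (the same profile whose thresholds produced the labels);
    both stages use an RBF kernel.  C and gamma default to values large
    enough that the machines interpolate the deterministic grid labeling
    (the labels carry no noise, so a tight fit is the intended behaviour).
    Deterministic for a fixed grid and seed.
    """
    labels = list(labels)
    if len(labels) != len(grid):
        raise ValueError("labels/grid length mismatch")
    present = set(labels)
    needed = {TriageColor.RED, TriageColor.YELLOW, TriageColor.GREEN}
    if not needed <= present:
        missing = ", ".join(sorted(c.value for c in needed - present))
        raise TrainingError(f"training labels missing class(es): {missing}")

    profile = profile or ReferenceProfile.default()
    ranges = {sign: profile.range_for(sign) for sign in Sign}
    rng = np.random.default_rng(seed)
    X = np.asarray(grid.cases, float)
    y = np.asarray([label.value for label in labels])
    # Shuffle for libsvm's working-set heuristics; the fitted machine is
    # still deterministic for a fixed seed.
    order = rng.permutation(len(y))
    X, y = X[order], y[order]
    Z = band_deviation(X, ranges)

    # Stage A: +1 = not-red (the "better" side), so the decision function
    # increases with survival.
    y_a = (y != TriageColor.RED.value).astype(int)
    svc_a = SVC(kernel="rbf", C=C, gamma=gamma).fit(Z, y_a)

    not_red = y_a == 1
    # Stage B: +1 = green among the not-red cases.
    y_b = (y[not_red] == TriageColor.GREEN.value).astype(int)
    svc_b = SVC(kernel="rbf", C=C, gamma=gamma).fit(Z[not_red], y_b)

    stage_a = RbfStage.from_svc(svc_a)
    stage_b = RbfStage.from_svc(svc_b)
    d_a = stage_a.decision_function(Z)
    d_b = stage_b.decision_function(Z[not_red])
    s_a = float(np.median(np.abs(d_a))) or 1.0
    s_b = float(np.median(np.abs(d_b))) or 1.0

    return SurvivalModel(
        ranges=ranges,
        stage_a=stage_a,
        stage_b=stage_b,
        margin_scales=(s_a, s_b),
        seed=seed,
    )


def survival_chance(model: SurvivalModel, case: VitalSnapshot) -> int:
    """Chance of survival (integer percent) for a fully observed snapshot.

    Defined only at 100 % reliability, i.e. all four signs present.  The
    value always lies inside the band of the predicted class; a case the
    model deems green returns exactly 100.
    """
    missing = [s.value for s in Sign if case.value_of(s) is None]
    if missing:
        raise ValueError(
            "survival chance requires all four signs; missing: " + ", ".join(missing)
        )
    x = np.array([[case.rr, case.hr, case.sbp, case.spo2]])
    return int(model.chance(x)[0])


def band_compliance(
    model: SurvivalModel,
    grid: CaseGrid,
    labels: Sequence[TriageColor] | None = None,
    profile: ReferenceProfile | None = None,
) -> dict:
    """Audit calibrated outputs against the triage labels and their bands.

    Reports per-color case counts, the fraction of calibrated outputs inside
    the band of their *triage* label (post-clamp), and the fraction of cases
    whose pre-clamp predicted class agrees with the label (diagnostic for
    the raw classifier, before band clamping hides mistakes).
    """
    if labels is None:
        labels = label_grid(grid, profile or ReferenceProfile.default())
    labels = list(labels)
    chances = model.chance(grid.cases)
    predicted = model.predict_color(grid.cases)

    counts = {
        c.value: 0 for c in (TriageColor.RED, TriageColor.YELLOW, TriageColor.GREEN)
    }
    in_band = 0
    for label, chance in zip(labels, chances):
        counts[label.value] += 1
        lo, hi = BANDS[label]
        if lo <= chance <= hi:
            in_band += 1
    agree = sum(p is l for p, l in zip(predicted, labels))
    n = len(labels)
    return {
        "n_cases": n,
        "counts": counts,
        "fraction_in_band": in_band / n,
        "pre_clamp_agreement": agree / n,
    }
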