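"""Binding strength in base-pair units from NF vs reference length.

Over the 20-40 bp range the mean NF falls linearly with the number of base
pairs in the shear reference duplex, so binding strength can be expressed
on a DNA length scale: the reference length at which NF = 0.5 is the
duplex whose rupture stability matches the protein-DNA bond, and the
difference in matched lengths between two motifs converts their strength
difference into "equivalent base pairs".  The same conversion falls out
directly when a low-affinity condition at one reference length is equal
within errors to a high-affinity condition at another: the strength gap is
then simply the reference-length gap (the matched-pair reading).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateModelError, InsufficientDataError, NoMatchError
from .nfstats import NFEstimate, equal_within_errors

__all__ = [
    "ConditionNF",
    "LinearNFModel",
    "MatchedLength",
    "EquivalentBpResult",
    "fit_linear_nf_model",
    "matched_reference_length",
    "equivalent_bp_difference",
    "calibration_report",
    "halving_ratio",
]

MATCHED_NF = 0.5  # NF at which reference duplex and sample bond are equally stable


@dataclass(frozen=True)
class ConditionNF:
    """One measured condition: a motif probed against one reference length."""

    motif_label: str
    reference_n_bp: int
    estimate: NFEstimate

    def __post_init__(self) -> None:
        if self.reference_n_bp < 1:
            raise ValueError("reference_n_bp must be >= 1")


@dataclass(frozen=True)
class LinearNFModel:
    """Least-squares line NF(n_bp) = intercept + slope * n_bp for one motif."""

    motif_label: str
    slope: float
    intercept: float
    fit_range: tuple[float, float]

    def predict(self, n_bp: float) -> float:
        return self.intercept + self.slope * n_bp

    def in_range(self, n_bp: float) -> bool:
        return self.fit_range[0] <= n_bp <= self.fit_range[1]


@dataclass(frozen=True)
class MatchedLength:
    """Reference length solving NF = 0.5, with an extrapolation flag."""

    length_bp: float
    extrapolated: bool


@dataclass(frozen=True)
class EquivalentBpResult:
    """Strength difference between two motifs expressed in DNA base pairs."""

    motif_a: str
    motif_b: str
    delta_bp: float
    method: str  # "matched_pair" | "linear_model"
    detail: tuple = ()


def fit_linear_nf_model(
    points: Sequence[tuple[float, float]], motif_label: str = ""
) -> LinearNFModel:
    """Ordinary least squares of mean NF against reference length.

    ``points`` are (reference_n_bp, nf_mean) pairs; zeroed conditions must
    be excluded by the caller.  Two points give the exact interpolating
    line.
    """
    if len({x for x, _ in points}) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct reference lengths to fit a line, got {points!r}"
        )
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    slope, intercept = np.polyfit(x, y, 1)
    return LinearNFModel(
        motif_label=motif_label,
        slope=float(slope),
        intercept=float(intercept),
        fit_range=(float(x.min()), float(x.max())),
    )


def matched_reference_length(model: LinearNFModel, target_nf: float = MATCHED_NF) -> MatchedLength:
    """Reference length at which the model predicts NF = ``target_nf``.

    That length is the duplex whose stability matches the protein-DNA bond.
    Lengths outside the fitted range are returned flagged as extrapolation
    (the linearity is only established inside the range).
    """
    # slopes below ~1e-12 NF/bp are numerically indistinguishable from flat
    if abs(model.slope) < 1e-12:
        raise DegenerateModelError(
            f"model for {model.motif_label!r} has zero slope; NF={target_nf} unreachable"
        )
    length = (target_nf - model.intercept) / model.slope
    return MatchedLength(length_bp=float(length), extrapolated=not model.in_range(length))


def _fitted(conditions: Sequence[ConditionNF]) -> list[ConditionNF]:
    return [c for c in conditions if c.estimate.status == "fitted"]


def equivalent_bp_difference(
    conditions: Sequence[ConditionNF], method: str = "matched_pair"
) -> EquivalentBpResult:
    """Express the strength gap between two motifs in equivalent base pairs.

    ``matched_pair`` (default) looks for cross-motif condition pairs that
    are equal within errors; the strength gap is then the reference-length
    gap of the best such pair (smallest mean difference).  ``linear_model``
    fits a line per motif and differences the NF = 0.5 matched lengths;
    it needs at least two reference lengths per motif but does not rely on
    a lucky overlap.
    """
    fitted = _fitted(conditions)
    if method == "matched_pair":
        qualifying: list[tuple[float, ConditionNF, ConditionNF]] = []
        gaps: list[str] = []
        for a, b in itertools.combinations(fitted, 2):
            if a.motif_label == b.motif_label:
                continue
            diff = abs(a.estimate.nf_mean - b.estimate.nf_mean)
            bound = a.estimate.nf_sd + b.estimate.nf_sd
            gaps.append(
                f"{a.motif_label}@{a.reference_n_bp}bp vs "
                f"{b.motif_label}@{b.reference_n_bp}bp: |dNF|={diff:.3f} bound={bound:.3f}"
            )
            if equal_within_errors(a.estimate, b.estimate):
                qualifying.append((diff, a, b))
        if not qualifying:
            raise NoMatchError(
                "no cross-motif pair is equal within errors; pairwise gaps: "
                + "; ".join(gaps)
            )
        _, a, b = min(qualifying, key=lambda t: t[0])
        return EquivalentBpResult(
            motif_a=a.motif_label,
            motif_b=b.motif_label,
            delta_bp=float(abs(a.reference_n_bp - b.reference_n_bp)),
            method="matched_pair",
            detail=(a, b),
        )
    if method == "linear_model":
        by_motif: dict[str, list[ConditionNF]] = {}
        for c in fitted:
            by_motif.setdefault(c.motif_label, []).append(c)
        models = {}
        for motif, conds in by_motif.items():
            points = [(c.reference_n_bp, c.estimate.nf_mean) for c in conds]
            if len({p[0] for p in points}) >= 2:
                models[motif] = fit_linear_nf_model(points, motif)
        if len(models) != 2:
            raise InsufficientDataError(
                "linear_model needs exactly two motifs with >= 2 reference lengths; "
                f"got models for {sorted(models)}"
            )
        (ma, model_a), (mb, model_b) = sorted(models.items())
        la = matched_reference_length(model_a)
        lb = matched_reference_length(model_b)
        return EquivalentBpResult(
            motif_a=ma,
            motif_b=mb,
            delta_bp=float(abs(la.length_bp - lb.length_bp)),
            method="linear_model",
            detail=((model_a, la), (model_b, lb)),
        )
    raise ValueError(f"unknown method {method!r}")


def calibration_report(estimates: Sequence[NFEstimate]) -> dict:
    """JSON-serializable calibration summary from per-pad estimates.

    Aggregates pads by (motif, reference length) — averaging replicate pads
    of the same condition — then runs both equivalent-bp methods.  A method
    that cannot be applied is reported with its error message instead of
    aborting the report.
    """
    groups: dict[tuple[str, int], list[NFEstimate]] = {}
    for e in estimates:
        if e.status == "failed":
            continue
        groups.setdefault((e.motif_label, e.reference_n_bp), []).append(e)
    if not groups:
        raise InsufficientDataError("no fitted or zeroed pads to calibrate from")

    conditions: list[ConditionNF] = []
    cond_rows = []
    for (motif, n_bp), ests in sorted(groups.items()):
        fitted = [e for e in ests if e.status == "fitted"]
        if fitted:
            mean = float(np.mean([e.nf_mean for e in fitted]))
            sd = float(np.mean([e.nf_sd for e in fitted]))
            pooled = NFEstimate(
                pad_id=fitted[0].pad_id, motif_label=motif, reference_n_bp=n_bp,
                nf_mean=mean, nf_sd=sd,
                n_pixels=int(sum(e.n_pixels for e in fitted)), status="fitted",
            )
        else:  # all replicates zeroed: no transfer signal above background
            mean, sd = 0.0, None
            pooled = NFEstimate(
                pad_id=ests[0].pad_id, motif_label=motif, reference_n_bp=n_bp,
                nf_mean=0.0, nf_sd=None,
                n_pixels=int(sum(e.n_pixels for e in ests)), status="zeroed",
            )
        conditions.append(ConditionNF(motif, n_bp, pooled))
        cond_rows.append(
            {"motif_label": motif, "reference_n_bp": n_bp, "nf_mean": mean,
             "nf_sd": sd, "status": pooled.status, "n_pads": len(ests)}
        )

    report: dict = {"conditions": cond_rows, "methods": {}}
    for method in ("matched_pair", "linear_model"):
        try:
            res = equivalent_bp_difference(conditions, method=method)
        except (NoMatchError, InsufficientDataError, DegenerateModelError) as exc:
            report["methods"][method] = {"error": str(exc)}
            continue
        entry: dict = {
            "motif_a": res.motif_a, "motif_b": res.motif_b, "delta_bp": res.delta_bp,
        }
        if method == "linear_model":
            entry["models"] = [
                {
                    "motif_label": model.motif_label,
                    "slope": model.slope,
                    "intercept": model.intercept,
                    "fit_range": list(model.fit_range),
                    "matched_length_bp": matched.length_bp,
                    "extrapolated": matched.extrapolated,
                }
                for model, matched in res.detail
            ]
        else:
            entry["pair"] = [
                {"motif_label": c.motif_label, "reference_n_bp": c.reference_n_bp,
                 "nf_mean": c.estimate.nf_mean, "nf_sd": c.estimate.nf_sd}
                for c in res.detail
            ]
        report["methods"][method] = entry
    return report


def halving_ratio(model_points: Sequence[tuple[float, float]]) -> float:
    """NF(2L) / NF(L) from exactly two points at lengths L and 2L.

    A ratio near 0.5 is the signature of the linear NF-length relation over
    a doubling of the reference duplex.
    """
    if len(model_points) != 2:
        raise ValueError("exactly two (length, nf) points required")
    (l1, nf1), (l2, nf2) = sorted(model_points)
    if l2 != 2 * l1:
        raise ValueError(f"lengths must be in a 2:1 ratio, got {l1} and {l2}")
    return nf2 / nf1
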