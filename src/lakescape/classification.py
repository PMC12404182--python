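"""Three-tier climate-vulnerability classification and future projection.

Watersheds within a mountain range are clustered on ln(x+1)-transformed mean
historical GDD with k-means constrained a priori to three clusters, labelled
cold / transitional / hot by ascending cluster center.  A linear discriminant
on the same (standardized) feature then scores projected period GDD and
returns posterior tier-membership probabilities, so vulnerability class can
be tracked across future climatology periods.  Models are fitted per range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .exceptions import DomainError, ModelError
from .velocity import transform_response

__all__ = [
    "TIER_ORDER",
    "TierModel",
    "mean_historical_gdd",
    "kmeans_tiers",
    "fit_discriminant",
    "resubstitution_accuracy",
    "predict_membership",
    "fit_tier_models",
]

TIER_ORDER = ("cold", "transitional", "hot")


@dataclass
class TierModel:
    """Per-range tier model: k-means centers plus discriminant + scaler."""

    region: str
    centers: np.ndarray  # 3 ascending centers on the ln(x+1) GDD scale
    assignments: pd.DataFrame  # watershed_id, ln_gdd, tier (training labels)
    scaler_mean: float = float("nan")
    scaler_sd: float = float("nan")
    lda: LinearDiscriminantAnalysis | None = None
    accuracy: float = float("nan")
    center_ties: bool = False
    inertia: float = float("nan")
    _extra: dict = field(default_factory=dict, repr=False)


def mean_historical_gdd(dd: pd.DataFrame) -> pd.DataFrame:
    """Per-watershed mean annual GDD over the historical window, ln(x+1).

    Columns out: ``watershed_id``, ``region``, ``mean_gdd``, ``ln_gdd``.
    """
    g = (
        dd.groupby(["watershed_id", "region"], sort=True)["gdd"]
        .mean()
        .reset_index(name="mean_gdd")
    )
    g["ln_gdd"] = transform_response(g["mean_gdd"].to_numpy(), "ln_gdd_plus1")
    return g


def kmeans_tiers(
    values: Sequence[float],
    restarts: int = 25,
    seed: int = 0,
    region: str = "",
) -> TierModel:
    """Cluster 1-D transformed mean GDD into three tiers with k-means.

    Lloyd's algorithm, best of ``restarts`` seeded random initializations by
    within-cluster sum of squares.  Centers are sorted ascending and mapped
    to cold / transitional / hot; ties between centers are broken by data
    order and flagged.  Requires >= 3 distinct values.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise ModelError("k-means with k=3 needs >= 3 distinct values")
    km = KMeans(
        n_clusters=3, n_init=restarts, init="random", random_state=seed,
        algorithm="lloyd",
    ).fit(x.reshape(-1, 1))
    raw_centers = km.cluster_centers_.ravel()
    order = np.argsort(raw_centers, kind="stable")  # stable sort breaks ties by index
    centers = raw_centers[order]
    ties = bool(np.any(np.diff(centers) == 0))
    tier_of_raw = {int(order[i]): TIER_ORDER[i] for i in range(3)}
    tiers = [tier_of_raw[int(l)] for l in km.labels_]
    assignments = pd.DataFrame({"ln_gdd": x, "tier": tiers})
    return TierModel(
        region=region,
        centers=centers,
        assignments=assignments,
        center_ties=ties,
        inertia=float(km.inertia_),
    )


def fit_discriminant(
    ln_gdd: Sequence[float],
    tiers: Sequence[str],
    region: str = "",
) -> TierModel:
    """Linear discriminant on standardized ln(x+1) mean GDD.

    Standardization parameters are estimated on the historical training
    values and stored; projected inputs are later scaled with this same
    scaler so warming shifts the feature rather than being rescaled away.
    Priors are empirical class frequencies.  Every present tier needs >= 2
    members and >= 2 tiers must be present.
    """
    x = np.asarray(ln_gdd, dtype=float)
    y = np.asarray(tiers, dtype=object)
    counts = pd.Series(y).value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ModelError(f"tier(s) with < 2 members: {sorted(thin.index)}")
    if len(counts) < 2:
        raise ModelError("discriminant needs >= 2 tiers present")
    mean, sd = float(x.mean()), float(x.std(ddof=0))
    if sd <= 0:
        raise ModelError("zero variance in training feature")
    z = (x - mean) / sd
    lda = LinearDiscriminantAnalysis().fit(z.reshape(-1, 1), y)
    model = TierModel(
        region=region,
        centers=np.sort(
            pd.DataFrame({"x": x, "t": y}).groupby("t")["x"].mean().to_numpy()
        ),
        assignments=pd.DataFrame({"ln_gdd": x, "tier": y}),
        scaler_mean=mean,
        scaler_sd=sd,
        lda=lda,
    )
    model.accuracy = resubstitution_accuracy(model, x, y)
    return model


def resubstitution_accuracy(model: TierModel, ln_gdd, tiers) -> float:
    """Fraction of training points whose predicted tier matches the k-means tier."""
    if model.lda is None:
        raise ModelError("discriminant not fitted")
    z = (np.asarray(ln_gdd, dtype=float) - model.scaler_mean) / model.scaler_sd
    pred = model.lda.predict(z.reshape(-1, 1))
    return float(np.mean(pred == np.asarray(tiers, dtype=object)))


def predict_membership(
    model: TierModel, projected: pd.DataFrame, gdd_col: str = "gdd"
) -> pd.DataFrame:
    """Posterior tier membership for projected period GDD.

    ``projected`` needs ``watershed_id``, ``period`` and a GDD column; GDD is
    ln(x+1)-transformed, standardized with the model's stored historical
    scaler and scored by the discriminant.  Columns out: ``watershed_id``,
    ``time_period``, ``tier``, ``p_cold``, ``p_transitional``, ``p_hot``.
    """
    if model.lda is None or not np.isfinite(model.scaler_sd):
        raise ModelError("model has no fitted discriminant/scaler")
    g = np.asarray(projected[gdd_col], dtype=float)
    if np.any(g < 0):
        raise DomainError("projected GDD must be >= 0")
    z = (transform_response(g, "ln_gdd_plus1") - model.scaler_mean) / model.scaler_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        proba = model.lda.predict_proba(z.reshape(-1, 1))
    classes = list(model.lda.classes_)
    out = pd.DataFrame(
        {
            "watershed_id": projected["watershed_id"].to_numpy(),
            "time_period": projected["period"].to_numpy(),
        }
    )
    for tier in TIER_ORDER:
        out[f"p_{tier}"] = (
            proba[:, classes.index(tier)] if tier in classes else 0.0
        )
    p = out[[f"p_{t}" for t in TIER_ORDER]].to_numpy()
    out.insert(2, "tier", [TIER_ORDER[i] for i in np.argmax(p, axis=1)])
    return out


def fit_tier_models(
    historical_means: pd.DataFrame,
    restarts: int = 25,
    seed: int = 0,
) -> dict[str, TierModel]:
    """k-means tiers + discriminant for every region of a mean-GDD table."""
    models: dict[str, TierModel] = {}
    for region, g in historical_means.groupby("region", sort=True):
        km = kmeans_tiers(g["ln_gdd"].to_numpy(), restarts=restarts, seed=seed,
                          region=region)
        model = fit_discriminant(
            g["ln_gdd"].to_numpy(), km.assignments["tier"].to_numpy(), region=region
        )
        model.centers = km.centers
        model.center_ties = km.center_ties
        model.inertia = km.inertia
        model.assignments = km.assignments.assign(
            watershed_id=g["watershed_id"].to_numpy()
        )[["watershed_id", "ln_gdd", "tier"]]
        models[region] = model
    return models
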