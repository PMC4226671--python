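"""Prognosis signature: Cox-filtered CpGs, two-cluster training, centroid transfer.

Training on a test cohort proceeds as: (1) keep CpG units whose univariate
Cox regression against disease-free survival has Wald p below ``alpha``
(default 5%, no multiple-testing correction); (2) hierarchically cluster
the patients on those CpGs (Euclidean distance, Ward linkage, per-CpG
median imputation for the distance computation only) and cut the dendrogram
at its main branches into two groups; (3) name the cluster with the higher
mean methylation "high" and assign good/bad prognosis labels by comparing
the clusters' Kaplan-Meier curves.  Validation cohorts are transferred by
nearest-centroid assignment over each patient's observed CpGs.

Reports carry the quantities a survival comparison of two prognosis groups
needs: log-rank p, the bad-vs-good hazard ratio with its 95% CI, and an
analysis-of-deviance p comparing the Cox model with age, gender, uN and the
grouping against the model without the grouping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .meth_io import filter_missing_samples
from .survival import CoxError, cox_fit, deviance_compare, kaplan_meier, logrank

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierModel",
    "ValidationReport",
    "filter_cpgs_by_dfs",
    "cluster_two_groups",
    "train_classifier",
    "assign_nearest_centroid",
    "evaluate_cohort",
]


@dataclass
class ClassifierModel:
    """Selected CpGs, the two training centroids, and the prognosis label map."""

    selected_cpgs: list[str]
    centroid_high: pd.Series
    centroid_low: pd.Series
    label_map: dict[str, str]  # {"high": "good"|"bad", "low": ...}
    alpha: float = 0.05
    distance: str = "euclidean"
    linkage_method: str = "ward"

    def __post_init__(self):
        if sorted(self.label_map) != ["high", "low"]:
            raise ValueError("label_map must have exactly the keys 'high' and 'low'")
        if sorted(self.label_map.values()) != ["bad", "good"]:
            raise ValueError("label_map must be a bijection onto {good, bad}")

    def to_json(self, path) -> None:
        payload = {
            "selected_cpgs": self.selected_cpgs,
            "centroid_high": self.centroid_high.round(10).to_dict(),
            "centroid_low": self.centroid_low.round(10).to_dict(),
            "label_map": self.label_map,
            "alpha": self.alpha,
            "distance": self.distance,
            "linkage_method": self.linkage_method,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        cpgs = d["selected_cpgs"]
        return cls(
            selected_cpgs=cpgs,
            centroid_high=pd.Series(d["centroid_high"]).reindex(cpgs),
            centroid_low=pd.Series(d["centroid_low"]).reindex(cpgs),
            label_map=d["label_map"],
            alpha=d["alpha"],
            distance=d["distance"],
            linkage_method=d["linkage_method"],
        )


@dataclass
class ValidationReport:
    assignments: pd.Series  # patient -> "good"/"bad"
    excluded: dict[str, str]
    logrank_p: float
    logrank_chi2: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    cox_p: float
    deviance_p: float | None
    deviance_stat: float | None
    group_sizes: dict[str, int]
    cpg_overlap: list[str] = field(default_factory=list)
    cpg_selected_here: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "assignments": self.assignments.to_dict(),
            "excluded": self.excluded,
            "logrank_p": self.logrank_p,
            "logrank_chi2": self.logrank_chi2,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci95": list(self.hr_ci95),
            "cox_p": self.cox_p,
            "deviance_p": self.deviance_p,
            "deviance_stat": self.deviance_stat,
            "group_sizes": self.group_sizes,
            "cpg_overlap": self.cpg_overlap,
            "cpg_selected_here": self.cpg_selected_here,
        }


def filter_cpgs_by_dfs(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """CpG units whose univariate Cox Wald p against DFS is below alpha.

    Each CpG is fitted on its complete cases.  CpGs without variation (or
    otherwise unfittable) are skipped with a warning and never selected.
    Returned in matrix (input) order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    missing_surv = [p for p in matrix.columns if p not in survival.index]
    if missing_surv:
        raise KeyError(f"patients without survival data: {missing_surv}")
    selected = []
    for cpg in matrix.index:
        x = matrix.loc[cpg].dropna()
        if len(x) < 3:
            logger.warning("CpG %s skipped: fewer than 3 observed patients", cpg)
            continue
        surv = survival.loc[x.index]
        try:
            fit = cox_fit(x.rename("meth").to_frame(), surv)
        except CoxError as exc:
            logger.warning("CpG %s skipped: %s", cpg, exc)
            continue
        if fit.p_wald[0] < alpha:
            selected.append(cpg)
    if not selected:
        raise ValueError(
            "no CpG passed the DFS Cox filter; inspect the matrix and survival table"
        )
    return selected


def cluster_two_groups(matrix: pd.DataFrame):
    """Cut a Ward dendrogram of the patients at its main branches.

    ``matrix`` is CpG × patient, restricted to the selected CpGs.  Missing
    values are imputed by the per-CpG median for the distance computation
    only; centroids are computed from observed values.  Returns
    (labels, linkage matrix, centroids) where labels maps patient to
    "high"/"low" and centroids is a dict of per-CpG means.
    """
    if matrix.shape[1] < 4:
        raise ValueError("clustering needs at least 4 patients")
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 selected CpGs")
    X = matrix.T  # patients × CpGs
    med = matrix.median(axis=1)
    X_imp = X.fillna(med)
    Z = linkage(X_imp.to_numpy(dtype=float), method="ward", metric="euclidean")
    cut = fcluster(Z, t=2, criterion="maxclust")
    c1 = X.index[cut == 1]
    c2 = X.index[cut == 2]
    if len(c1) <= 1 or len(c2) <= 1:
        warnings.warn("main-branch cut produced a singleton cluster", stacklevel=2)
    cent1 = matrix[c1].mean(axis=1)
    cent2 = matrix[c2].mean(axis=1)
    if cent1.mean() >= cent2.mean():
        high, low, cent_high, cent_low = c1, c2, cent1, cent2
    else:
        high, low, cent_high, cent_low = c2, c1, cent2, cent1
    labels = pd.Series("low", index=X.index, name="cluster")
    labels.loc[high] = "high"
    return labels, Z, {"high": cent_high, "low": cent_low}


def _group_report(prognosis: pd.Series, survival: pd.DataFrame):
    """Log-rank, bad-vs-good Cox HR with CI, and analysis of deviance."""
    surv = survival.loc[prognosis.index]
    lr = logrank(prognosis, surv)
    bad = (prognosis == "bad").astype(float).rename("bad_prognosis")
    uni = cox_fit(bad.to_frame(), surv)
    hr = float(uni.hazard_ratios[0])
    ci = tuple(float(v) for v in uni.ci95[0])
    cox_p = float(uni.p_wald[0])

    covs = pd.DataFrame(
        {
            "age": surv["age"].astype(float),
            "gender_male": (surv["gender"] == "male").astype(float),
            "uN": surv["uN"].astype(float),
        },
        index=surv.index,
    )
    full_covs = covs.assign(bad_prognosis=bad)
    complete = full_covs.notna().all(axis=1)
    dev_p = dev_stat = None
    try:
        full = cox_fit(full_covs.loc[complete], surv.loc[complete])
        reduced = cox_fit(covs.loc[complete], surv.loc[complete])
        dev_stat, _, dev_p = deviance_compare(full, reduced)
    except CoxError as exc:
        logger.warning("analysis of deviance unavailable: %s", exc)
    return lr, hr, ci, cox_p, dev_p, dev_stat


def train_classifier(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    missing_threshold: float = 0.6,
) -> tuple[ClassifierModel, dict]:
    """Learn the prognosis signature on a test cohort.

    Composes the missingness filter, the per-CpG DFS Cox filter and the
    two-group Ward clustering; the cluster with the better Kaplan-Meier
    curve (larger restricted mean survival over the shared follow-up) is
    labelled the good-prognosis group.  Returns the model plus a training
    report (cluster labels, log-rank p, HR and CI, deviance p).
    """
    mat = filter_missing_samples(matrix, missing_threshold)
    if alpha >= 1.0:
        selected = list(mat.index)
    else:
        selected = filter_cpgs_by_dfs(mat, survival, alpha)
    labels, Z, centroids = cluster_two_groups(mat.loc[selected])

    surv = survival.loc[labels.index]
    horizon = float(surv["time_months"].max())
    rmst = {
        cl: kaplan_meier(surv, (labels == cl).to_numpy()).restricted_mean(horizon)
        for cl in ("high", "low")
    }
    good_cluster = "high" if rmst["high"] >= rmst["low"] else "low"
    label_map = {
        "high": "good" if good_cluster == "high" else "bad",
        "low": "good" if good_cluster == "low" else "bad",
    }
    model = ClassifierModel(
        selected_cpgs=selected,
        centroid_high=centroids["high"],
        centroid_low=centroids["low"],
        label_map=label_map,
        alpha=alpha,
    )
    prognosis = labels.map(label_map)
    lr, hr, ci, cox_p, dev_p, dev_stat = _group_report(prognosis, survival)
    report = {
        "n_patients": int(len(labels)),
        "n_selected_cpgs": len(selected),
        "selected_cpgs": selected,
        "cluster_labels": labels.to_dict(),
        "prognosis_labels": prognosis.to_dict(),
        "label_map": label_map,
        "group_sizes": prognosis.value_counts().to_dict(),
        "logrank_p": float(lr.p),
        "logrank_chi2": float(lr.chi_square),
        "hazard_ratio": hr,
        "hr_ci95": list(ci),
        "cox_p": cox_p,
        "deviance_p": dev_p,
        "deviance_stat": dev_stat,
        "restricted_mean_months": rmst,
    }
    return model, report


def assign_nearest_centroid(
    patient: pd.Series,
    model: ClassifierModel,
    min_observed: float = 0.4,
) -> str | None:
    """Assign one patient to the nearer training centroid.

    Distances are root-mean-square differences over the patient's observed
    selected CpGs, so patients with different missingness are comparable.
    Returns "high" or "low"; an exact tie goes to "high".  Patients with
    fewer than ``min_observed`` of the selected CpGs observed return None.
    """
    x = patient.reindex(model.selected_cpgs)
    obs = x.notna()
    if obs.mean() < min_observed:
        return None
    xo = x[obs].to_numpy(dtype=float)
    d_high = np.sqrt(np.mean((xo - model.centroid_high[obs].to_numpy()) ** 2))
    d_low = np.sqrt(np.mean((xo - model.centroid_low[obs].to_numpy()) ** 2))
    # ties (within float noise) go to the high-methylation cluster
    return "high" if d_high <= d_low + 1e-12 else "low"


def evaluate_cohort(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    model: ClassifierModel,
    missing_threshold: float = 0.6,
    min_observed: float = 0.4,
    alpha_overlap: float | None = 0.05,
) -> ValidationReport:
    """Transfer the signature to a cohort and compare the resulting groups.

    Patients failing the cohort missingness filter or observing fewer than
    ``min_observed`` of the signature CpGs are excluded with a reason.  The
    report carries log-rank p, the bad-vs-good HR with 95% CI, the
    analysis-of-deviance p (age + gender + uN + group vs. without group),
    and — when ``alpha_overlap`` is set — the overlap between this cohort's
    own DFS-correlated CpGs and the training signature.
    """
    excluded: dict[str, str] = {}
    before = set(matrix.columns)
    mat = filter_missing_samples(matrix, missing_threshold)
    for pid in before - set(mat.columns):
        excluded[pid] = f"more than {missing_threshold:.0%} of CpG units missing"

    assignments = {}
    for pid in mat.columns:
        cl = assign_nearest_centroid(mat[pid], model, min_observed)
        if cl is None:
            excluded[pid] = (
                f"fewer than {min_observed:.0%} of signature CpGs observed"
            )
        else:
            assignments[pid] = model.label_map[cl]
    prognosis = pd.Series(assignments, name="prognosis")
    if prognosis.nunique() < 2:
        raise ValueError(
            "nearest-centroid assignment produced a single group; "
            "no survival comparison is possible"
        )
    surv = survival.loc[prognosis.index]
    if surv["event"].sum() == 0:
        raise ValueError("validation cohort has zero events")
    lr, hr, ci, cox_p, dev_p, dev_stat = _group_report(prognosis, survival)

    overlap, selected_here = [], []
    if alpha_overlap is not None:
        try:
            selected_here = filter_cpgs_by_dfs(mat, survival, alpha_overlap)
        except ValueError:
            selected_here = []
        overlap = [c for c in model.selected_cpgs if c in selected_here]
    return ValidationReport(
        assignments=prognosis,
        excluded=excluded,
        logrank_p=float(lr.p),
        logrank_chi2=float(lr.chi_square),
        hazard_ratio=hr,
        hr_ci95=ci,
        cox_p=cox_p,
        deviance_p=dev_p,
        deviance_stat=dev_stat,
        group_sizes=prognosis.value_counts().to_dict(),
        cpg_overlap=overlap,
        cpg_selected_here=selected_here,
    )
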