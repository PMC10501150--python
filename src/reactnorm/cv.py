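"""Leave-one-year-out genomic prediction (CV0 / CV00).

A test year is held out; the remaining years train the environmental
gradient, the merit predictor and the genomic model.  CV0 evaluates all
phenotyped hybrids of the test year (they may have training records from
other years); CV00 evaluates only hybrids with no training records at all.
Predicted test-environment GEBVs are compared against either the
within-environment identity-covariance BLUPs or the GEBVs of a model fitted
on every year (the whole-dataset reference).  Accuracy is the per-environment
Pearson correlation; bias is the slope of reference-on-prediction minus one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM
from .gradient import (EnvironmentGradient, fit_baseline_blup, identity_blup,
                       scale_gradient)
from .merit import build_features, fit_merit_model, predict_merit
from .params import gebv_trajectories
from .rnm import ModelSpec, RNMFit, fit_rnm

__all__ = ["CVScheme", "CVResult", "split_cv", "single_env_blup",
           "accuracy_and_bias", "run_cv", "run_cv_year",
           "whole_dataset_reference", "cv_summary_table", "GBLUP_SPEC"]

# the plain-GBLUP arm: intercept-only random regression, homogeneous
# residual, no broad-environment term
GBLUP_SPEC = ModelSpec(order=0, residual="homogeneous", include_be=False)


@dataclass(frozen=True)
class CVScheme:
    """One cross-validation cell: held-out year, scheme, gradient, model."""

    test_year: int
    scheme: str = "CV0"                  # CV0 | CV00
    gradient_mode: str = "predicted"     # predicted | known
    model_arm: str = "RNM"               # RNM | GBLUP

    def __post_init__(self):
        if self.scheme not in ("CV0", "CV00"):
            raise ValueError("scheme must be CV0 or CV00")
        if self.gradient_mode not in ("predicted", "known"):
            raise ValueError("gradient_mode must be predicted or known")
        if self.model_arm not in ("RNM", "GBLUP"):
            raise ValueError("model_arm must be RNM or GBLUP")


@dataclass
class CVResult:
    scheme: CVScheme
    reference: str                       # single_env_blup | whole_dataset
    per_env: pd.DataFrame                # env_id, n, accuracy, bias, theta
    skipped_envs: list = field(default_factory=list)

    def summary(self) -> dict:
        acc = self.per_env["accuracy"]
        return {
            "mean": float(acc.mean()), "min": float(acc.min()),
            "max": float(acc.max()),
            "sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            "bias": float(self.per_env["bias"].mean()),
            "n_envs": int(len(acc)),
        }


def split_cv(phenotypes: pd.DataFrame, scheme: CVScheme
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into training years and the held-out test year.

    Training records are all records of the other years under both schemes.
    The CV0 test set holds every record of the test year; CV00 keeps only
    records of hybrids that have no record in any training year.
    """
    years = set(phenotypes["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two years for leave-one-year-out")
    if scheme.test_year not in years:
        raise ValueError(f"test year {scheme.test_year} not present")
    is_test_year = phenotypes["year"] == scheme.test_year
    train = phenotypes[~is_test_year]
    test = phenotypes[is_test_year]
    if scheme.scheme == "CV00":
        seen = set(train["hybrid_id"])
        test = test[~test["hybrid_id"].isin(seen)]
        if len(test) == 0:
            raise ValueError(
                "CV00 test set is empty: every test-year hybrid also has "
                "training records; simulate lower hybrid overlap across "
                "years")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def single_env_blup(env_records: pd.DataFrame, y_col: str = "yield_Mg_ha"
                    ) -> tuple[pd.Series, dict]:
    """Within-environment hybrid BLUPs with identity covariance."""
    return identity_blup(env_records, y_col=y_col)


def accuracy_and_bias(pred, ref) -> tuple[float, float]:
    """Per-environment prediction accuracy and bias.

    Accuracy is the Pearson correlation of prediction and reference; bias is
    the slope of the regression of the reference on the prediction minus
    one, so a prediction identical to its reference has bias exactly 0.
    """
    p = np.asarray(pred, float)
    r = np.asarray(ref, float)
    if len(p) != len(r) or len(p) < 2:
        raise ValueError("need two vectors of equal length >= 2")
    if p.std() == 0 or r.std() == 0:
        raise ValueError("zero-variance vector")
    acc = float(np.corrcoef(p, r)[0, 1])
    pc, rc = p - p.mean(), r - r.mean()
    slope = float(pc @ rc) / float(pc @ pc)
    return acc, slope - 1.0


def whole_dataset_reference(phenotypes: pd.DataFrame, grm: GRM,
                            spec: ModelSpec | None = None,
                            y_col: str = "yield_Mg_ha"
                            ) -> tuple[pd.DataFrame, RNMFit,
                                       EnvironmentGradient]:
    """GEBV matrix from a model fitted on all years.

    Returns (hybrids x environments GEBV, the fit, the all-years gradient).
    """
    fit1 = fit_baseline_blup(phenotypes, y_col=y_col)
    grad = scale_gradient(fit1.beta)
    fit = fit_rnm(phenotypes, grad, grm, spec, y_col=y_col)
    gebv = gebv_trajectories(fit.a_hat, T=fit.T, env_ids=fit.env_ids)
    return gebv, fit, grad


def run_cv_year(phenotypes: pd.DataFrame, grm: GRM, test_year: int,
                model_arm: str = "RNM", gradient_mode: str = "predicted",
                schemes=("CV0", "CV00"),
                references=("single_env_blup",),
                weather: pd.DataFrame | None = None,
                soil: pd.DataFrame | None = None,
                spec: ModelSpec | None = None,
                whole_gebv: pd.DataFrame | None = None,
                seed: int = 0, min_hybrids: int = 3,
                y_col: str = "yield_Mg_ha",
                merit_kwargs: dict | None = None) -> list[CVResult]:
    """Evaluate one (test year, model arm, gradient mode) training fit.

    The genomic model and the test-environment gradient are fitted once on
    the training years and then evaluated for every requested scheme and
    reference, which is substantially cheaper than refitting per cell.
    """
    base_scheme = CVScheme(test_year=test_year, scheme="CV0",
                           gradient_mode=gradient_mode, model_arm=model_arm)
    train, test_cv0 = split_cv(phenotypes, base_scheme)
    if spec is None:
        spec = GBLUP_SPEC if model_arm == "GBLUP" else ModelSpec()
    elif model_arm == "GBLUP":
        spec = GBLUP_SPEC

    fit_train = fit_baseline_blup(train, y_col=y_col)
    grad_train = scale_gradient(fit_train.beta)

    test_envs = sorted(test_cv0["env_id"].unique())
    if model_arm == "GBLUP":
        # intercept-only model: theta never enters the prediction
        theta_test = pd.Series(0.0, index=test_envs)
    elif gradient_mode == "predicted":
        if weather is None or soil is None:
            raise ValueError("predicted gradient mode needs weather and "
                             "soil tables")
        feats = build_features(weather, soil).table
        train_envs = [e for e in grad_train.table["env_id"]
                      if e in feats.index]
        mm = fit_merit_model(
            feats.loc[train_envs],
            pd.Series(grad_train.theta_map()).loc[train_envs],
            seed=seed, **(merit_kwargs or {}))
        pred = predict_merit(mm, feats.loc[[e for e in test_envs
                                            if e in feats.index]])
        theta_test = pred["theta"]
    else:
        fit_all = fit_baseline_blup(phenotypes, y_col=y_col)
        beta_test = fit_all.beta.loc[test_envs]
        theta_test = pd.Series(grad_train.scale(beta_test, clip=True),
                               index=test_envs)

    model_fit = fit_rnm(train, grad_train, grm, spec, y_col=y_col)

    train_hybrids = set(train["hybrid_id"])
    pred_cache: dict = {}
    results = []
    for sch in schemes:
        for ref_name in references:
            rows, skipped = [], []
            for env in test_envs:
                env_rec = test_cv0[test_cv0["env_id"] == env]
                hybs = sorted(env_rec["hybrid_id"].unique())
                if sch == "CV00":
                    hybs = [h for h in hybs if h not in train_hybrids]
                if env not in theta_test.index or len(hybs) < min_hybrids:
                    skipped.append(env)
                    continue
                th = float(theta_test.loc[env])
                if th not in pred_cache:
                    pred_cache[th] = gebv_trajectories(
                        model_fit.a_hat, theta=[th]).iloc[:, 0]
                pred = pred_cache[th].reindex(hybs)

                if ref_name == "single_env_blup":
                    try:
                        ref, _ = single_env_blup(env_rec, y_col=y_col)
                    except ValueError:
                        skipped.append(env)
                        continue
                    ref = ref.reindex(hybs)
                elif ref_name == "whole_dataset":
                    if whole_gebv is None:
                        raise ValueError("pass whole_gebv for the "
                                         "whole-dataset reference")
                    if env not in whole_gebv.columns:
                        skipped.append(env)
                        continue
                    ref = whole_gebv[env].reindex(hybs)
                else:
                    raise ValueError(f"unknown reference {ref_name!r}")

                ok = pred.notna() & ref.notna()
                if ok.sum() < min_hybrids:
                    skipped.append(env)
                    continue
                try:
                    acc, bias = accuracy_and_bias(pred[ok], ref[ok])
                except ValueError:
                    skipped.append(env)
                    continue
                rows.append({"env_id": env, "n": int(ok.sum()),
                             "accuracy": acc, "bias": bias, "theta": th})
            if skipped:
                warnings.warn(
                    f"{sch}/{ref_name} year {test_year}: environments "
                    f"skipped: {skipped}")
            scheme = CVScheme(test_year=test_year, scheme=sch,
                              gradient_mode=gradient_mode,
                              model_arm=model_arm)
            results.append(CVResult(
                scheme=scheme, reference=ref_name,
                per_env=pd.DataFrame(
                    rows, columns=["env_id", "n", "accuracy", "bias",
                                   "theta"]),
                skipped_envs=skipped))
    return results


def run_cv(phenotypes: pd.DataFrame, grm: GRM, scheme: CVScheme,
           reference: str = "single_env_blup", **kwargs) -> CVResult:
    """One cross-validation cell (see run_cv_year for the batched form)."""
    res = run_cv_year(phenotypes, grm, scheme.test_year,
                      model_arm=scheme.model_arm,
                      gradient_mode=scheme.gradient_mode,
                      schemes=(scheme.scheme,), references=(reference,),
                      **kwargs)
    return res[0]


def cv_summary_table(results: list[CVResult]) -> pd.DataFrame:
    """Stack CVResult objects into a summary table (one row per arm)."""
    rows = []
    for res in results:
        s = res.summary()
        rows.append({
            "scheme": res.scheme.scheme,
            "model": res.scheme.model_arm,
            "gradient": res.scheme.gradient_mode,
            "test_year": res.scheme.test_year,
            "reference": res.reference, **s,
        })
    return pd.DataFrame(rows)
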