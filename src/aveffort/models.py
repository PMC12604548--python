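"""Linear mixed models of effort and recognition with quadratic SNR terms.

Three condition-level outcomes are modelled: keyword-recognition proportion,
peak pupil dilation, and frontal midline theta power.  Fixed effects are a
centered linear SNR term, a quadratic SNR term (effort outcomes only),
modality (treatment-coded, AO reference, so the modality coefficients are AV
offsets), and the modality-by-SNR interactions; subject identity enters as a
random intercept, estimated by REML.  Centering SNR at the design mean
(-6 dB) makes the linear and quadratic regressors exactly orthogonal over
the design {-12, -8, -4, 0}.

The visual-only condition never enters these models.  Per-coefficient tests
are Wald z tests from the REML fixed-effect covariance (no Satterthwaite
degree-of-freedom correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "center_snr",
    "fit_lmm",
    "wald_tests",
    "COEF_NAMES",
]

#: Canonical coefficient names, in design-matrix order.
COEF_NAMES = ("intercept", "mod", "snr", "mod:snr", "snr2", "mod:snr2")

OUTCOME_COLUMNS = {
    "score_proportion": "score_proportion",
    "ppd": "ppd",
    "theta_db": "theta_db",
}


def center_snr(snr_db, center: float = -6.0):
    """Centered SNR, ``snr - center``."""
    out = np.asarray(snr_db, dtype=float) - center
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model and with what fixed-effect structure."""

    outcome: str  # "score_proportion" | "ppd" | "theta_db"
    center_snr: float = -6.0
    quadratic: bool | None = None  # default: quadratic for effort outcomes only

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.quadratic is None:
            object.__setattr__(self, "quadratic", self.outcome != "score_proportion")


@dataclass
class MixedModelFit:
    """REML fixed-effect estimates, their covariance, variance components."""

    beta: dict  # canonical name -> estimate
    vcov: np.ndarray  # fixed-effect covariance, ordered like names
    names: tuple[str, ...]
    sigma2_subject: float
    sigma2_resid: float
    n_obs: int
    converged: bool
    outcome: str
    center_snr: float

    def se(self) -> dict:
        d = np.sqrt(np.diag(self.vcov))
        return dict(zip(self.names, d))

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "center_snr": self.center_snr,
            "beta": self.beta,
            "se": self.se(),
            "vcov": self.vcov.tolist(),
            "names": list(self.names),
            "sigma2_subject": self.sigma2_subject,
            "sigma2_resid": self.sigma2_resid,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixedModelFit":
        return cls(
            beta=dict(d["beta"]),
            vcov=np.asarray(d["vcov"], float),
            names=tuple(d["names"]),
            sigma2_subject=float(d["sigma2_subject"]),
            sigma2_resid=float(d["sigma2_resid"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            outcome=d["outcome"],
            center_snr=float(d["center_snr"]),
        )


class ModelFitError(RuntimeError):
    """Raised on singular designs or failed REML convergence."""


def _canonical_names(quadratic: bool) -> tuple[str, ...]:
    if quadratic:
        return COEF_NAMES
    return ("intercept", "mod", "snr", "mod:snr")


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the random-intercept LMM for one outcome on a condition-level table.

    ``table`` needs columns ``subject``, ``modality`` (AO/AV; VO rows are
    rejected), ``snr_db``, and the outcome column.  One aggregated
    observation per subject x condition is expected.  Estimation is REML via
    statsmodels ``MixedLM``; non-convergence raises :class:`ModelFitError`.
    """
    col = OUTCOME_COLUMNS[spec.outcome]
    if col not in table.columns:
        raise ValueError(f"table lacks outcome column {col!r}")
    if (table["modality"] == "VO").any():
        raise ValueError("VO rows must not enter the statistical models")
    if not set(table["modality"]) <= {"AO", "AV"}:
        raise ValueError("modality must be AO or AV")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a random intercept")

    df = table.copy()
    df["snr_c"] = center_snr(df["snr_db"].to_numpy(), spec.center_snr)
    df["snr_c2"] = df["snr_c"] ** 2
    mod_term = "C(modality, Treatment('AO'))"
    terms = [mod_term, "snr_c", f"{mod_term}:snr_c"]
    if spec.quadratic:
        terms += ["snr_c2", f"{mod_term}:snr_c2"]
    formula = f"{col} ~ " + " + ".join(terms)

    rename = {
        "Intercept": "intercept",
        f"{mod_term}[T.AV]": "mod",
        "snr_c": "snr",
        f"{mod_term}[T.AV]:snr_c": "mod:snr",
        "snr_c2": "snr2",
        f"{mod_term}[T.AV]:snr_c2": "mod:snr2",
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"])
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ModelFitError(f"mixed-model construction failed: {err}") from err
        # near-boundary variance components occasionally trip an optimizer;
        # try alternatives before giving up
        res = None
        last_err: Exception | None = None
        for method in (None, "lbfgs", "powell"):
            try:
                res = (model.fit(reml=True) if method is None
                       else model.fit(reml=True, method=method))
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            if res.converged:
                break
    if res is None:
        raise ModelFitError(f"mixed-model fit failed: {last_err}") from last_err
    if not res.converged:
        raise ModelFitError("REML estimation did not converge")

    fe = res.fe_params
    names = _canonical_names(bool(spec.quadratic))
    by_canonical = {rename[k]: float(v) for k, v in fe.items()}
    beta = {name: by_canonical[name] for name in names}
    cov = res.cov_params()
    fe_labels = list(fe.index)
    cov_fe = cov.loc[fe_labels, fe_labels].to_numpy()
    inv = {v: k for k, v in rename.items()}
    idx = [fe_labels.index(inv[name]) for name in names]
    vcov = cov_fe[np.ix_(idx, idx)]
    vcov = 0.5 * (vcov + vcov.T)

    return MixedModelFit(
        beta=beta,
        vcov=vcov,
        names=names,
        sigma2_subject=float(res.cov_re.iloc[0, 0]),
        sigma2_resid=float(res.scale),
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        outcome=spec.outcome,
        center_snr=spec.center_snr,
    )


def wald_tests(fit: MixedModelFit) -> pd.DataFrame:
    """Per-coefficient Wald z statistics and two-sided normal p values."""
    if not fit.converged:
        raise ValueError("fit did not converge; tests unavailable")
    se = np.sqrt(np.diag(fit.vcov))
    if np.any(se == 0):
        raise ValueError("zero coefficient variance; Wald statistic undefined")
    est = np.array([fit.beta[n] for n in fit.names])
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": fit.names, "estimate": est, "se": se, "z": z, "p": p}
    ).set_index("term")
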