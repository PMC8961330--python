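"""Continuous familial loading score (FLS).

The FLS condenses a participant's family history of depression/anxiety into a
single continuous score.  For each first-degree relative *j* with observation
age *x*, a likelihood ratio compares two hypotheses about the participant:

* the participant is at familial risk — relatives then carry a lifetime
  prevalence ``a`` (0.50 by default, the prevalence among first-degree
  relatives of affected persons);
* the participant is not at familial risk — relatives then carry a lifetime
  prevalence ``b`` (0.134 by default, half of the 26.8% Dutch population
  lifetime prevalence).

First onsets are taken to occur uniformly over the age window ``[d, c]``
(5-65 years by default), so that by age *x* a fraction

    u(x) = clip((x - d) / (c - d), 0, 1)

of a relative's lifetime risk has been expressed.  Under this construction

* an **affected** relative contributes LR = (a·u)/(b·u) = a/b, independent of
  age (the window factor cancels);
* an **unaffected** relative contributes LR = (1 - a·u)/(1 - b·u), which is 1
  for a relative too young to have entered the risk window (no evidence) and
  decreases towards (1-a)/(1-b) as the window is fully traversed — an elderly
  unaffected relative is strong evidence *against* familial loading.

The FLS is the common (base-10) logarithm of the product of the per-relative
likelihood ratios; it is computed as a sum of logs for numerical stability.
An empty family gives FLS = 0 (empty product).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .family import MAX_AGE, Family, MissingDataError, validate_relatives_frame

logger = logging.getLogger(__name__)

__all__ = [
    "FLSParameters",
    "FLSResult",
    "onset_fraction",
    "lr_affected",
    "lr_unaffected",
    "compute_fls",
    "score_families",
    "FamilialLoadingScorer",
]


@dataclass(frozen=True)
class FLSParameters:
    """The four scalar constants of the likelihood-ratio construction.

    a : lifetime prevalence of depression/anxiety given a positive family
        history (default 0.50)
    b : lifetime prevalence given a negative family history (default 0.134,
        i.e. half the 26.8% population lifetime prevalence)
    c, d : upper / lower limit (years) of the age window in which most first
        onsets appear (defaults 65 and 5)
    """

    a: float = 0.50
    b: float = 0.134
    c: float = 65.0
    d: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.b < self.a < 1.0):
            raise ValueError(
                f"require 0 < b < a < 1, got a={self.a}, b={self.b}; "
                "with b >= a the likelihood-ratio directions invert"
            )
        if not (0.0 <= self.d < self.c):
            raise ValueError(f"require 0 <= d < c, got c={self.c}, d={self.d}")


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(age < 0):
        raise ValueError("age must be finite and non-negative")
    if np.any(age > MAX_AGE):
        raise ValueError(f"implausible age > {MAX_AGE}")
    return age


def onset_fraction(age, params: FLSParameters | None = None):
    """Fraction of the first-onset risk window [d, c] traversed by ``age``.

    Clamped to [0, 1]: ages below d have not entered the window, ages above c
    contribute the fully-traversed value.
    """
    p = params or FLSParameters()
    age = _check_age(age)
    u = np.clip((age - p.d) / (p.c - p.d), 0.0, 1.0)
    return float(u) if u.ndim == 0 else u


def lr_affected(age, params: FLSParameters | None = None) -> float:
    """Likelihood ratio contributed by an affected relative of given age.

    Under the uniform-onset construction the cumulative risks a·u and b·u
    share the window factor u, so the ratio is a/b at any age inside the
    window.  An affection recorded before the window opens (age <= d) is
    internally inconsistent data; a/b is still returned but a warning is
    emitted.
    """
    p = params or FLSParameters()
    u = onset_fraction(age, p)
    if np.any(np.asarray(u) == 0.0):
        warnings.warn(
            "affected relative recorded at an age at or below the onset-window "
            f"lower limit d={p.d}; treating as affected with LR = a/b",
            stacklevel=2,
        )
    return p.a / p.b


def lr_unaffected(age, params: FLSParameters | None = None):
    """Likelihood ratio contributed by an unaffected relative of given age.

    (1 - a·u)/(1 - b·u): equals 1 at u = 0 (an unaffected child carries no
    evidence) and decreases monotonically to (1-a)/(1-b) at u = 1.
    """
    p = params or FLSParameters()
    u = onset_fraction(age, p)
    lr = (1.0 - p.a * np.asarray(u)) / (1.0 - p.b * np.asarray(u))
    return float(lr) if np.ndim(lr) == 0 else lr


@dataclass
class FLSResult:
    """FLS for one family, with per-relative audit detail."""

    fls: float
    per_relative_log_lr: list[float] = field(default_factory=list)

    @property
    def overall_lr(self) -> float:
        """Product-scale overall likelihood ratio (10**fls); audit only."""
        return float(10.0 ** self.fls)


def compute_fls(family: Family, params: FLSParameters | None = None) -> FLSResult:
    """FLS of one family: sum over relatives of log10 of the per-relative LR."""
    p = params or FLSParameters()
    logs: list[float] = []
    for r in family.relatives:
        if r.affected is None:
            raise MissingDataError(
                f"{family.proband_id}/{r.label}: unresolved affected status"
            )
        if r.affected:
            lr = lr_affected(r.age_years, p)
        else:
            lr = lr_unaffected(r.age_years, p)
        logs.append(float(np.log10(lr)))
    return FLSResult(fls=float(sum(logs)), per_relative_log_lr=logs)


def _per_relative_log_lr(age: np.ndarray, affected: np.ndarray, p: FLSParameters) -> np.ndarray:
    u = np.clip((age - p.d) / (p.c - p.d), 0.0, 1.0)
    log_aff = np.log10(p.a / p.b)
    log_unaff = np.log10(1.0 - p.a * u) - np.log10(1.0 - p.b * u)
    return np.where(affected, log_aff, log_unaff)


def score_families(
    relatives: pd.DataFrame,
    params: FLSParameters | None = None,
    *,
    proband_ids=None,
) -> pd.DataFrame:
    """Vectorised scoring of a relative-level table.

    Parameters
    ----------
    relatives
        Relative-level table (see :mod:`famloading.family` for the schema).
    params
        FLS constants; defaults to the depression/anxiety set.
    proband_ids
        Optional full participant roster.  Roster members without any relative
        rows receive fls = 0, fh = 0, n_relatives = 0 (with a logged warning);
        a relative-level CSV cannot otherwise express an empty family.

    Returns
    -------
    DataFrame with columns proband_id, fh (0/1), fls, n_relatives, n_affected.
    """
    p = params or FLSParameters()
    df = validate_relatives_frame(relatives)
    df["_loglr"] = _per_relative_log_lr(
        df["age_years"].to_numpy(), df["affected"].to_numpy(), p
    )
    grp = df.groupby("proband_id", sort=False)
    out = pd.DataFrame(
        {
            "fls": grp["_loglr"].sum(),
            "n_relatives": grp.size(),
            "n_affected": grp["affected"].sum().astype(int),
        }
    )
    out["fh"] = (out["n_affected"] > 0).astype(int)
    out = out.reset_index()[["proband_id", "fh", "fls", "n_relatives", "n_affected"]]
    if proband_ids is not None:
        roster = pd.Index(pd.unique(pd.Series(list(proband_ids)).astype(out["proband_id"].dtype)))
        missing = roster.difference(out["proband_id"])
        if len(missing):
            logger.warning(
                "%d proband(s) have no relative rows; scored as FH-, FLS=0", len(missing)
            )
            empty = pd.DataFrame(
                {
                    "proband_id": list(missing),
                    "fh": 0,
                    "fls": 0.0,
                    "n_relatives": 0,
                    "n_affected": 0,
                }
            )
            out = pd.concat([out, empty], ignore_index=True)
        out = out.set_index("proband_id").loc[roster]
        out.index.name = "proband_id"
        out = out.reset_index()
    return out


class FamilialLoadingScorer(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer from relative tables to familial scores.

    Parameters are the FLS constants (``a``, ``b``, ``c``, ``d``); they are not
    estimated from data, so :meth:`fit` only validates them and the input
    schema.  :meth:`transform` maps a relative-level DataFrame to the
    participant-level score table (``proband_id, fh, fls, n_relatives,
    n_affected``).

    Examples
    --------
    >>> scorer = FamilialLoadingScorer().fit(relatives_df)
    >>> scores = scorer.transform(relatives_df)
    """

    def __init__(self, a: float = 0.50, b: float = 0.134, c: float = 65.0, d: float = 5.0):
        self.a = a
        self.b = b
        self.c = c
        self.d = d

    def fit(self, X: pd.DataFrame, y=None) -> "FamilialLoadingScorer":
        self.params_ = FLSParameters(a=self.a, b=self.b, c=self.c, d=self.d)
        validate_relatives_frame(X)
        return self

    def transform(self, X: pd.DataFrame, proband_ids=None) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            raise NotFittedError("FamilialLoadingScorer is not fitted; call fit first")
        return score_families(X, self.params_, proband_ids=proband_ids)
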