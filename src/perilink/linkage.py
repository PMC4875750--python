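"""The three probabilistic scoring algorithms.

Fellegi–Sunter
    Each field carries an m-probability (chance a true-match pair agrees on
    it) and a u-probability (chance a non-match pair agrees by accident).
    Agreement contributes the natural-log likelihood ratio w_m = ln(m/u),
    disagreement w_nm = ln((1-m)/(1-u)); a pair's weight is the sum over
    observed fields.  A missing outcome contributes nothing, so an
    all-missing pair scores 0 rather than artificially low.

EM estimation
    When m, u and the match prevalence p are unknown they are fitted as a
    two-component mixture over the observed comparison vectors by
    expectation–maximisation, treating missing outcomes as uninformative
    (skipped in the likelihood product).  Scoring then reuses the
    Fellegi–Sunter sum with the fitted table.

EpiLink
    Each field carries an error rate e (chance the recorded value is wrong)
    and an average value frequency f (collision probability); its weight is
    w = log2((1-e)/f).  A pair's score is the weighted proportion of
    agreeing fields among the observed ones, Σ w·s / Σ w ∈ [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from perilink.comparison import ComparisonVector, ComparisonVectors

logger = logging.getLogger(__name__)

_EPS = 1e-8  # keep log-weights finite during EM updates


@dataclass
class ProbabilityTable:
    """Per-field (m, u) probabilities.

    m and u must lie strictly inside (0, 1): m = 1 or u = 0 would give an
    infinite agreement weight and m = 0 or u = 1 an infinite disagreement
    weight, so such values are rejected outright rather than clamped.
    """

    m: dict
    u: dict

    def __post_init__(self) -> None:
        if set(self.m) != set(self.u):
            raise ValueError("m and u must cover the same fields")
        for f in self.m:
            m, u = float(self.m[f]), float(self.u[f])
            if not (0.0 < m < 1.0):
                raise ValueError(f"m[{f!r}]={m} outside (0, 1)")
            if not (0.0 < u < 1.0):
                raise ValueError(f"u[{f!r}]={u} outside (0, 1)")

    @property
    def fields(self) -> list:
        return list(self.m)

    def subset(self, fields) -> "ProbabilityTable":
        return ProbabilityTable(
            {f: self.m[f] for f in fields}, {f: self.u[f] for f in fields}
        )


@dataclass
class WeightTable:
    """Per-field log-weights: w_m on agreement, w_nm on disagreement."""

    w_m: dict
    w_nm: dict

    @property
    def fields(self) -> list:
        return list(self.w_m)

    def rounded(self, ndigits: int = 4) -> "WeightTable":
        return WeightTable(
            {f: round(v, ndigits) for f, v in self.w_m.items()},
            {f: round(v, ndigits) for f, v in self.w_nm.items()},
        )


@dataclass
class ScoredPair:
    """A candidate pair with its linkage weight under one algorithm."""

    cohort_id: object
    episode_id: object
    weight: float
    algorithm: str


def fs_weights(pt: ProbabilityTable) -> WeightTable:
    """Fellegi–Sunter log-weights from an m/u table.

    w_m = ln(m/u) and w_nm = ln((1-m)/(1-u)); a field with m = u gets
    w_m = w_nm = 0 and therefore never influences a score.
    """
    w_m = {f: float(np.log(self_m / self_u)) for f, (self_m, self_u) in _iter_mu(pt)}
    w_nm = {
        f: float(np.log((1.0 - self_m) / (1.0 - self_u)))
        for f, (self_m, self_u) in _iter_mu(pt)
    }
    return WeightTable(w_m=w_m, w_nm=w_nm)


def _iter_mu(pt: ProbabilityTable):
    for f in pt.fields:
        yield f, (float(pt.m[f]), float(pt.u[f]))


def _score_matrix(matrix: np.ndarray, wm: np.ndarray, wnm: np.ndarray) -> np.ndarray:
    agree = np.nan_to_num(matrix, nan=0.0)
    observed = ~np.isnan(matrix)
    return agree @ wm + ((1.0 - agree) * observed) @ wnm


def fs_score(cv: ComparisonVector, wt: WeightTable) -> ScoredPair:
    """Sum of per-field weights for one pair: w_m on agree, w_nm on
    disagree, nothing on missing."""
    total = 0.0
    for f, o in cv.outcomes.items():
        if o is None:
            continue
        if f not in wt.w_m:
            raise ValueError(f"weight table lacks field {f!r}")
        total += wt.w_m[f] if o == 1 else wt.w_nm[f]
    return ScoredPair(cv.pair[0], cv.pair[1], total, "fs")


def fs_score_many(cvs: ComparisonVectors, wt: WeightTable, algorithm: str = "fs") -> pd.DataFrame:
    """Score every pair; returns columns cohort_id, episode_id, weight, algorithm."""
    missing = [f for f in cvs.fields if f not in wt.w_m]
    if missing:
        raise ValueError(f"weight table lacks field(s) {missing}")
    wm = np.array([wt.w_m[f] for f in cvs.fields])
    wnm = np.array([wt.w_nm[f] for f in cvs.fields])
    out = cvs.pairs.copy()
    out["weight"] = _score_matrix(cvs.matrix, wm, wnm)
    out["algorithm"] = algorithm
    return out


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


@dataclass
class EMParams:
    """Fitted two-class mixture parameters for the comparison space."""

    m: dict
    u: dict
    p: float
    converged: bool
    iterations: int
    message: str = ""
    loglik: list = dc_field(default_factory=list)

    def probability_table(self) -> ProbabilityTable:
        clip = lambda x: float(np.clip(x, _EPS, 1.0 - _EPS))
        return ProbabilityTable(
            {f: clip(v) for f, v in self.m.items()},
            {f: clip(v) for f, v in self.u.items()},
        )


def em_fit(
    cvs: ComparisonVectors,
    init: EMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    expected_matches: int | None = None,
) -> EMParams:
    """Fit (m, u, p) by EM over the comparison vectors.

    The model: a pair is a true match with prevalence p; given match
    status, field outcomes are independent Bernoulli with rate m (match) or
    u (non-match); missing outcomes are skipped in the likelihood.  The
    E-step computes each pair's match responsibility, the M-step
    re-estimates m, u as responsibility-weighted agreement rates over the
    pairs where the field is observed, and p as the mean responsibility.

    Degenerate inputs (every comparison pattern identical, or a mixture
    that collapses to p ∈ {0, 1}) carry no class information: the fit is
    returned with ``converged=False`` and a diagnostic message, and
    downstream scoring refuses it — the analogue of a linkage day on which
    the algorithm fails to converge and yields no matches.
    """
    X = cvs.matrix
    n, k = X.shape
    if n == 0:
        raise ValueError("no comparison vectors to fit")

    if np.unique(np.nan_to_num(X, nan=-1.0), axis=0).shape[0] == 1:
        return EMParams(
            m={f: np.nan for f in cvs.fields},
            u={f: np.nan for f in cvs.fields},
            p=np.nan,
            converged=False,
            iterations=0,
            message="degenerate input: all comparison patterns identical",
        )

    if init is not None:
        m = np.array([init.m[f] for f in cvs.fields], dtype=float)
        u = np.array([init.u[f] for f in cvs.fields], dtype=float)
        p = float(init.p)
    else:
        m = np.full(k, 0.9)
        u = np.full(k, 0.1)
        if expected_matches is not None:
            p = min(max(expected_matches / n, _EPS), 0.5)
        else:
            p = 0.01

    observed = ~np.isnan(X)
    agree = np.nan_to_num(X, nan=0.0)
    disagree = (1.0 - agree) * observed

    loglik: list[float] = []
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        mc = np.clip(m, _EPS, 1 - _EPS)
        uc = np.clip(u, _EPS, 1 - _EPS)
        log_match = agree @ np.log(mc) + disagree @ np.log1p(-mc) + np.log(p)
        log_non = agree @ np.log(uc) + disagree @ np.log1p(-uc) + np.log1p(-p)
        denom = np.logaddexp(log_match, log_non)
        loglik.append(float(denom.sum()))
        r = np.exp(log_match - denom)

        new_p = float(r.mean())
        w_obs_m = r @ observed
        w_obs_u = (1.0 - r) @ observed
        with np.errstate(invalid="ignore", divide="ignore"):
            new_m = np.where(w_obs_m > 0, (r @ agree) / w_obs_m, m)
            new_u = np.where(w_obs_u > 0, ((1.0 - r) @ agree) / w_obs_u, u)

        delta = max(
            float(np.max(np.abs(new_m - m))),
            float(np.max(np.abs(new_u - u))),
            abs(new_p - p),
        )
        m, u, p = new_m, new_u, new_p
        if p < _EPS or p > 1 - _EPS:
            message = f"mixture collapsed to p={p:.3g}"
            break
        if delta < tol:
            converged = True
            break
    else:
        message = f"max_iter={max_iter} reached (last delta {delta:.3g})"

    if not converged and not message:
        message = "stopped without convergence"
    return EMParams(
        m=dict(zip(cvs.fields, m)),
        u=dict(zip(cvs.fields, u)),
        p=p,
        converged=converged,
        iterations=it,
        message=message,
        loglik=loglik,
    )


def em_score(cv: ComparisonVector, params: EMParams) -> ScoredPair:
    """Fellegi–Sunter scoring with the EM-fitted table; refuses an
    unconverged fit."""
    if not params.converged:
        raise ValueError(f"EM parameters not converged: {params.message}")
    sp = fs_score(cv, fs_weights(params.probability_table()))
    sp.algorithm = "em"
    return sp


def em_score_many(cvs: ComparisonVectors, params: EMParams) -> pd.DataFrame:
    if not params.converged:
        raise ValueError(f"EM parameters not converged: {params.message}")
    return fs_score_many(cvs, fs_weights(params.probability_table()), algorithm="em")


# ---------------------------------------------------------------------------
# EpiLink
# ---------------------------------------------------------------------------


@dataclass
class EpiLinkSpec:
    """Per-field error rates e and average value frequencies f.

    The field weight is w = log2((1-e)/f); both e and f are specified in
    advance rather than estimated from the data being linked.
    """

    error_rate: dict
    avg_frequency: dict

    def __post_init__(self) -> None:
        if set(self.error_rate) != set(self.avg_frequency):
            raise ValueError("error_rate and avg_frequency must cover the same fields")
        for f in self.error_rate:
            e, fr = float(self.error_rate[f]), float(self.avg_frequency[f])
            if not (0.0 <= e < 1.0):
                raise ValueError(f"error_rate[{f!r}]={e} outside [0, 1)")
            if not (0.0 < fr <= 1.0):
                raise ValueError(f"avg_frequency[{f!r}]={fr} outside (0, 1]")

    @property
    def fields(self) -> list:
        return list(self.error_rate)

    def weights(self) -> dict:
        """Per-field weights log2((1-e)/f).

        A field whose weight is not positive (its values collide by chance
        at least as often as correctly-recorded values agree) carries no
        discriminating information and is excluded from scoring — the
        EpiLink analogue of an m = u field contributing nothing to a
        Fellegi–Sunter sum.  Keeping only positive weights also keeps the
        normalised score inside [0, 1].
        """
        raw = {
            f: float(np.log2((1.0 - self.error_rate[f]) / self.avg_frequency[f]))
            for f in self.error_rate
        }
        dropped = [f for f, w in raw.items() if w <= 0.0]
        if dropped:
            logger.debug("EpiLink: dropping non-positive-weight field(s) %s", dropped)
        return {f: w for f, w in raw.items() if w > 0.0}


def epilink_score(cv: ComparisonVector, spec: EpiLinkSpec) -> ScoredPair:
    """Normalised weighted similarity Σ w·s / Σ w over observed fields.

    Undefined when every outcome is missing; such pairs are skipped by the
    bulk scorer and rejected here.
    """
    w = spec.weights()
    num = den = 0.0
    for f, o in cv.outcomes.items():
        if o is None:
            continue
        if f not in spec.error_rate:
            raise ValueError(f"EpiLink spec lacks field {f!r}")
        wf = w.get(f, 0.0)
        num += wf * o
        den += wf
    if den == 0.0:
        raise ValueError("EpiLink score undefined: all outcomes missing")
    return ScoredPair(cv.pair[0], cv.pair[1], num / den, "epilink")


def epilink_score_many(cvs: ComparisonVectors, spec: EpiLinkSpec) -> pd.DataFrame:
    """Score every pair; all-missing pairs are dropped with a log entry."""
    missing = [f for f in cvs.fields if f not in spec.error_rate]
    if missing:
        raise ValueError(f"EpiLink spec lacks field(s) {missing}")
    w = spec.weights()
    wv = np.array([w.get(f, 0.0) for f in cvs.fields])
    observed = ~np.isnan(cvs.matrix)
    agree = np.nan_to_num(cvs.matrix, nan=0.0)
    den = observed @ wv
    num = agree @ wv
    ok = den > 0
    if (~ok).any():
        logger.info("skipping %d all-missing pair(s) in EpiLink scoring", int((~ok).sum()))
    out = cvs.pairs.loc[ok].copy()
    out["weight"] = num[ok] / den[ok]
    out["algorithm"] = "epilink"
    return out.reset_index(drop=True)
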