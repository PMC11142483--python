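"""Genome-wide Cox proportional-hazards scan on donor-recipient mismatch scores.

Each SNP's IBS mismatch score enters a Cox model for time to first acute rejection
together with the fixed clinical covariates (recipient age, gender, PRA status, HLA
mismatch count, prior non-kidney transplant).  The partial likelihood is maximized
by Newton iterations with step-halving; tied event times (expected with
day-resolution follow-up) use the Efron correction by default, Breslow optionally.

The solver is implemented here rather than delegated to a general survival package
because a genome-wide scan needs on the order of a millisecond per SNP: the risk-set
sums are cumulative sums over a single pre-sorted ordering that is shared by every
SNP in the scan, so only the mismatch column changes between fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .paired_io import COVARIATE_COLUMNS, PairedCohort
from .mismatch_qc import MismatchMatrix

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = chi2.ppf(0.5, df=1)  # ~0.45494


@dataclass
class CoxFit:
    """One fitted Cox model: per-term estimates plus fit diagnostics."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    n: int
    n_events: int
    loglik: float
    loglik_null: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.coef / self.se

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(lower, upper) hazard-ratio confidence bounds per term."""
        zq = norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [np.exp(self.coef - zq * self.se), np.exp(self.coef + zq * self.se)]
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_lower95": ci[:, 0],
                "hr_upper95": ci[:, 1],
                "z": self.wald_z,
                "p": self.p,
            },
            index=self.names,
        )


class CoxDesign:
    """Pre-sorted risk-set structure reused across many fits on the same outcome.

    Rows are sorted by decreasing follow-up time so every risk set is a prefix and
    all risk-set sums become cumulative sums.  Efron's correction expands each
    tied event group of size d into d rows with tie fractions l/d.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, tie_method: str = "efron"):
        if tie_method not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {tie_method!r}")
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        if np.isnan(time).any():
            raise ValueError("missing follow-up times")
        if event.sum() < 1:
            raise ValueError("at least one event is required")
        self.n = time.size
        self.n_events = int(event.sum())
        self.order = np.argsort(-time, kind="stable")
        self.t_sorted = time[self.order]
        self.e_sorted = event[self.order]
        self.event_rows = np.flatnonzero(self.e_sorted == 1)
        ev_times = self.t_sorted[self.event_rows]
        # contiguous groups of tied event times (descending order)
        starts = np.flatnonzero(np.concatenate(([True], np.diff(ev_times) != 0)))
        self.group_starts = starts
        sizes = np.diff(np.concatenate((starts, [self.event_rows.size])))
        self.group_sizes = sizes
        # risk-set boundary: last sorted index with time >= group's event time
        self.boundaries = np.searchsorted(-self.t_sorted, -ev_times[starts], side="right") - 1
        # expanded (group, tie-fraction) rows
        self.exp_group = np.repeat(np.arange(starts.size), sizes)
        if tie_method == "efron":
            self.exp_frac = np.concatenate([np.arange(d) / d for d in sizes])
        else:
            self.exp_frac = np.zeros(self.exp_group.size)

    def loglik_grad_info(self, X_sorted: np.ndarray, beta: np.ndarray):
        """Partial log-likelihood, gradient, and observed information at ``beta``.

        ``X_sorted`` must already be in this design's row order.
        """
        eta = X_sorted @ beta
        etac = eta - eta.max()  # the shift cancels exactly in the partial likelihood
        w = np.exp(etac)
        wX = w[:, None] * X_sorted
        cw0 = np.cumsum(w)
        cw1 = np.cumsum(wX, axis=0)
        cw2 = np.cumsum(wX[:, :, None] * X_sorted[:, None, :], axis=0)
        b = self.boundaries
        S0r, S1r, S2r = cw0[b], cw1[b], cw2[b]
        ev = self.event_rows
        gs = self.group_starts
        S0t = np.add.reduceat(w[ev], gs)
        S1t = np.add.reduceat(wX[ev], gs, axis=0)
        S2t = np.add.reduceat(wX[ev][:, :, None] * X_sorted[ev][:, None, :], gs, axis=0)
        g, f = self.exp_group, self.exp_frac
        denom = S0r[g] - f * S0t[g]
        num1 = S1r[g] - f[:, None] * S1t[g]
        num2 = S2r[g] - f[:, None, None] * S2t[g]
        mbar = num1 / denom[:, None]
        ll = float(etac[ev].sum() - np.log(denom).sum())
        U = X_sorted[ev].sum(axis=0) - mbar.sum(axis=0)
        info = (num2 / denom[:, None, None]).sum(axis=0) - mbar.T @ mbar
        return ll, U, info


def fit_cox(
    time,
    event,
    X,
    names: list[str] | None = None,
    tie_method: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
    design: CoxDesign | None = None,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton iterations with step-halving.

    Convergence requires the gradient norm to fall below ``tol``.  A coefficient
    escaping past |beta| = 20 is treated as separation: the fit is returned with
    ``converged=False`` and missing p-values.  A constant covariate raises a
    ``ValueError`` naming it.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != np.size(time):
        X = X.T
    n, p = X.shape
    names = names if names is not None else [f"x{i}" for i in range(p)]
    if np.isnan(X).any():
        raise ValueError("missing values in covariate matrix; drop incomplete rows first")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = names[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant covariate {bad!r}")
    des = design if design is not None else CoxDesign(time, event, tie_method)
    Xs = X[des.order]

    beta = np.zeros(p)
    ll, U, info = des.loglik_grad_info(Xs, beta)
    ll_null = ll
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(U) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(info + 1e-8 * np.eye(p), U)
        step = 1.0
        for _half in range(40):
            cand = beta + step * delta
            ll_new, U_new, info_new = des.loglik_grad_info(Xs, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, U, info = cand, ll_new, U_new, info_new
        if np.abs(beta).max() > 20.0:
            break
    separated = np.abs(beta).max() > 20.0
    if separated:
        converged = False
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    if converged:
        z = beta / se
        pvals = 2.0 * norm.sf(np.abs(z))
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    else:
        pvals = np.full(p, np.nan)
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        p=pvals,
        converged=converged,
        n=n,
        n_events=des.n_events,
        loglik=ll,
        loglik_null=ll_null,
    )


def cox_score_test(time, event, x, tie_method: str = "efron") -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for a single covariate; returns (chi2, p).

    With a binary group covariate and no tied event times this statistic equals
    the classical log-rank test on the two groups.
    """
    des = CoxDesign(time, event, tie_method)
    x = np.asarray(x, float).reshape(-1, 1)
    _, U, info = des.loglik_grad_info(x[des.order], np.zeros(1))
    stat = float(U[0] ** 2 / info[0, 0])
    return stat, float(chi2.sf(stat, df=1))


def cox_lrt(full: CoxFit, reduced: CoxFit) -> tuple[float, float]:
    """Likelihood-ratio test between nested fits; returns (chi2, p)."""
    df = len(full.names) - len(reduced.names)
    stat = 2.0 * (full.loglik - reduced.loglik)
    return stat, float(chi2.sf(stat, df=max(df, 1)))


def screen_covariates(
    time: np.ndarray, event: np.ndarray, C: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Drop clinical covariates that cannot be estimated in this sample.

    Two degeneracies are screened: constant columns, and monotone-likelihood
    separation (a rare binary covariate with no events on one side drives its
    coefficient to +/- infinity, e.g. prior transplant in a small cohort).  A
    separated *nuisance* covariate would otherwise poison every per-SNP fit, so it
    is removed with a logged warning and the scan proceeds with the rest.
    """
    keep = [j for j in range(C.shape[1]) if C[:, j].std() > 0]
    dropped = [names[j] for j in range(C.shape[1]) if j not in keep]
    while keep:
        fit = fit_cox(time, event, C[:, keep], [names[j] for j in keep], max_iter=40)
        sep = np.flatnonzero(np.abs(fit.coef) > 20.0)
        if sep.size == 0:
            break
        worst = keep[int(sep[np.argmax(np.abs(fit.coef[sep]))])]
        dropped.append(names[worst])
        keep = [j for j in keep if j != worst]
    if dropped:
        logger.warning("dropping inestimable clinical covariates: %s", ", ".join(dropped))
    return C[:, keep], [names[j] for j in keep]


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Per-SNP scan table plus scan-level metadata."""

    table: pd.DataFrame  # snp_id, chrom, pos, a0, a1, a1_freq, mean_mismatch, beta, se, hr, p, converged
    covariates: list[str]
    n_pairs: int
    n_events: int
    lambda_gc: float

    def pvalues(self) -> pd.Series:
        return self.table.set_index("snp_id")["p"]

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def genome_scan(
    cohort: PairedCohort,
    mismatch: MismatchMatrix,
    retained_snp_ids: list[str] | None = None,
    tie_method: str = "efron",
) -> ScanResult:
    """Fit the per-SNP mismatch Cox model over all retained SNPs.

    Pairs with incomplete phenotype rows are dropped with a logged count.  SNPs
    whose mismatch column has zero variance, or whose fit separates or fails, are
    flagged (``converged=False``, missing beta/p) and the scan continues.
    """
    pheno = cohort.phenotype
    needed = ["time_days", "event", *COVARIATE_COLUMNS]
    complete = ~pheno[needed].isna().any(axis=1).to_numpy()
    if not complete.all():
        logger.info("genome_scan: dropped %d pairs with incomplete covariates", (~complete).sum())
    pheno = pheno.loc[complete]
    scores_all = mismatch.scores[complete]

    time = pheno["time_days"].to_numpy(float)
    event = pheno["event"].to_numpy(int)
    C, covar_names = screen_covariates(
        time, event, pheno[list(COVARIATE_COLUMNS)].to_numpy(float), list(COVARIATE_COLUMNS)
    )
    design = CoxDesign(time, event, tie_method)
    names = ["mismatch", *covar_names]

    snp_index = {s: j for j, s in enumerate(mismatch.snp_ids)}
    ids = list(mismatch.snp_ids) if retained_snp_ids is None else list(retained_snp_ids)
    meta = cohort.snps.set_index("snp_id")

    rows = []
    for sid in ids:
        j = snp_index[sid]
        x = scores_all[:, j]
        beta = se = hr = pval = np.nan
        ok = False
        if np.isnan(x).any():
            keep = ~np.isnan(x)
            if keep.sum() >= 2 and event[keep].sum() >= 1 and np.nanstd(x[keep]) > 0:
                try:
                    fit = fit_cox(
                        time[keep],
                        event[keep],
                        np.column_stack([x[keep], C[keep]]),
                        names,
                        tie_method,
                    )
                    beta, se, hr, pval, ok = (
                        fit.coef[0],
                        fit.se[0],
                        fit.hr[0],
                        fit.p[0],
                        fit.converged,
                    )
                except (ValueError, np.linalg.LinAlgError):
                    ok = False
        elif x.std() > 0:
            try:
                fit = fit_cox(
                    time, event, np.column_stack([x, C]), names, tie_method, design=design
                )
                beta, se, hr, pval, ok = (
                    fit.coef[0],
                    fit.se[0],
                    fit.hr[0],
                    fit.p[0],
                    fit.converged,
                )
            except (ValueError, np.linalg.LinAlgError):
                ok = False
        m = meta.loc[sid]
        mean_mm = mismatch.mean_mismatch[j]
        rows.append(
            (sid, m["chrom"], m["pos"], m["a0"], m["a1"], m["alt_freq"], mean_mm, beta, se, hr, pval, ok)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "chrom",
            "pos",
            "a0",
            "a1",
            "a1_freq",
            "mean_mismatch",
            "beta",
            "se",
            "hr",
            "p",
            "converged",
        ],
    )
    pvals = table.loc[table["converged"], "p"].dropna().to_numpy()
    lam = genomic_inflation(pvals) if pvals.size else np.nan
    return ScanResult(
        table=table,
        covariates=covar_names,
        n_pairs=int(complete.sum()),
        n_events=int(event.sum()),
        lambda_gc=lam,
    )


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi-square over its null median."""
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 100:
        logger.warning("genomic inflation estimated from only %d p-values", p.size)
    chi = chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)
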