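"""Case-control association testing and meta-analysis.

Implements Firth (Jeffreys-prior penalized) logistic regression for
per-variant association — the penalty keeps estimates finite under the
complete separation that rare large-effect variants produce — plus
fixed-effects inverse-variance-weighted meta-analysis across cohorts,
two-round LD clumping with locus definition, and stepwise conditional
signal discovery with optional preconditioning covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

GW_THRESHOLD = 5e-8
#: MAF filters used for association scans (MHC-region vs genome-wide runs).
MAF_MIN_MHC = 0.01
MAF_MIN_GENOMEWIDE = 0.001


@dataclass(frozen=True)
class AssocResult:
    """Per-variant association estimate (alt-allele orientation)."""

    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    af: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be positive for {self.variant_id}")
        if abs(self.z - self.beta / self.se) > 1e-8:
            raise ValueError(f"z must equal beta/se for {self.variant_id}")


@dataclass(frozen=True)
class MetaResult:
    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    n_total: int
    inputs: tuple[AssocResult, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class ConditionalSignal:
    rank: int
    lead: str
    beta: float
    se: float
    p: float
    conditioning_set: tuple[str, ...]


@dataclass(frozen=True)
class Locus:
    index_id: str
    chrom: str
    start: int
    end: int
    members: tuple[str, ...]


# ---------------------------------------------------------------------------
# Firth logistic regression
# ---------------------------------------------------------------------------

def _check_design(x: np.ndarray, covars: np.ndarray | None, covar_names) -> None:
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dosage column")
    if covars is not None and covars.size:
        rank = np.linalg.matrix_rank(covars)
        if rank < covars.shape[1]:
            # identify a minimal set of offending columns by greedy QR
            bad = []
            kept: list[int] = []
            for j in range(covars.shape[1]):
                trial = covars[:, kept + [j]]
                if np.linalg.matrix_rank(trial) == len(kept) + 1:
                    kept.append(j)
                else:
                    bad.append(covar_names[j] if covar_names is not None else j)
            raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")


def _firth_fit(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solver for the Jeffreys-penalized likelihood.

    Maximizes ``l(b) + 0.5 * log det I(b)``; the modified score replaces the
    residual with ``y - p + h (0.5 - p)`` where ``h`` are hat-matrix leverages.
    Step-halving guards against penalized-likelihood decreases. Returns
    ``(beta, cov)`` with ``cov`` the inverse Fisher information at the optimum.
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_ll(b: np.ndarray) -> float:
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = expit(eta)
        W = p * (1 - p)
        _, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        XW = X * W[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular information matrix in Firth fit") from e
        # leverages of W^1/2 X
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], info_inv, X * np.sqrt(W)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        if np.linalg.norm(score) < tol:
            break
        step = info_inv @ score
        # step-halving on penalized log-likelihood decrease
        factor = 1.0
        for _half in range(25):
            cand = beta + factor * step
            ll_new = penalized_ll(cand)
            if ll_new >= ll_old - 1e-12:
                beta, ll_old = cand, ll_new
                break
            factor *= 0.5
        else:
            break
    eta = X @ beta
    p = expit(eta)
    W = p * (1 - p)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    return beta, cov


def firth_logistic(
    y: np.ndarray,
    x: np.ndarray,
    covars: pd.DataFrame | np.ndarray | None = None,
    variant_id: str = "variant",
) -> AssocResult:
    """Firth-penalized logistic association of a binary label with a dosage.

    Fits ``logit P(y=1) = b0 + beta * x + covariates`` by maximizing the
    Jeffreys-penalized likelihood; reports the Wald z and two-sided p for the
    dosage term. Estimates remain finite under complete separation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() < 0 or y.max() > 1 or len(np.unique(y)) < 2:
        raise ValueError("y must contain at least one case and one control")
    names = None
    if covars is not None:
        if isinstance(covars, pd.DataFrame):
            names = list(covars.columns)
            covars = covars.to_numpy(dtype=float)
        covars = np.atleast_2d(np.asarray(covars, dtype=float))
        if covars.shape[0] != len(y):
            covars = covars.T
    _check_design(x, covars, names)
    cols = [np.ones_like(x), x]
    if covars is not None and covars.size:
        cols.extend(covars.T)
    X = np.column_stack(cols)
    beta_vec, cov = _firth_fit(X, y)
    beta, se = float(beta_vec[1]), float(np.sqrt(cov[1, 1]))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssocResult(
        variant_id=variant_id, beta=beta, se=se, z=z, p=max(p, 5e-324),
        af=float(np.mean(x) / 2.0), n=len(y),
    )


def logistic_scan(y: np.ndarray, G: np.ndarray, max_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Fast per-variant plain-ML logistic fits, vectorized across variants.

    Fits ``logit P(y=1) = b0_v + b1_v * g_v`` independently for every column
    of ``G`` with closed-form 2x2 Newton steps. Returns ``(beta, se)`` arrays.
    Intended for scans where the Firth penalty is unnecessary (common
    variants, moderate effects), e.g. fine-mapping calibration runs.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    b0 = np.full(m, np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12)))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[None, :] + G * b1[None, :]
        p = expit(eta)
        r = y[:, None] - p
        w = p * (1 - p)
        u0 = r.sum(axis=0)
        u1 = (G * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * G).sum(axis=0)
        i11 = (w * G * G).sum(axis=0)
        det = i00 * i11 - i01 * i01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (i11 * u0 - i01 * u1) / det
        d1 = (-i01 * u0 + i00 * u1) / det
        # damp huge steps (separation guard)
        scale = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1)) / 5.0)
        b0 += d0 / scale
        b1 += d1 / scale
        if max(np.abs(u0).max(initial=0), np.abs(u1).max(initial=0)) < 1e-6:
            break
    eta = b0[None, :] + G * b1[None, :]
    w = expit(eta) * (1 - expit(eta))
    i00 = w.sum(axis=0)
    i01 = (w * G).sum(axis=0)
    i11 = (w * G * G).sum(axis=0)
    det = i00 * i11 - i01 * i01
    se = np.sqrt(np.maximum(i00 / np.maximum(det, 1e-300), 1e-300))
    return b1, se


def association_scan(
    y: np.ndarray,
    G: np.ndarray,
    variant_ids: list[str],
    covars: pd.DataFrame | np.ndarray | None = None,
    maf_min: float = 0.0,
) -> list[AssocResult]:
    """Firth association for every panel variant passing the MAF filter."""
    out = []
    for j, vid in enumerate(variant_ids):
        x = G[:, j]
        af = float(np.mean(x) / 2.0)
        maf = min(af, 1 - af)
        if maf < maf_min or np.ptp(x) == 0:
            continue
        out.append(firth_logistic(y, x, covars=covars, variant_id=vid))
    return out


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def ivw_meta(results: list[AssocResult]) -> MetaResult:
    """Fixed-effects inverse-variance-weighted combination of cohort results.

    ``beta = sum(w_i b_i) / sum(w_i)`` with ``w_i = se_i^-2`` and
    ``se = sum(w_i)^-1/2``. All inputs must refer to the same variant and
    allele orientation.
    """
    if not results:
        raise ValueError("need at least one cohort result")
    vid = results[0].variant_id
    if any(r.variant_id != vid for r in results):
        raise ValueError("mismatched variants in meta-analysis")
    w = np.array([r.se**-2 for r in results])
    b = np.array([r.beta for r in results])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    return MetaResult(
        variant_id=vid, beta=beta, se=se, z=z,
        p=float(max(2.0 * stats.norm.sf(abs(z)), 5e-324)),
        n_total=int(sum(r.n for r in results)), inputs=tuple(results),
    )


def meta_scan(per_cohort: list[list[AssocResult]]) -> list[MetaResult]:
    """Meta-analyze aligned per-cohort scans; variants missing from any
    cohort are combined over the cohorts that tested them."""
    by_id: dict[str, list[AssocResult]] = {}
    for scan in per_cohort:
        for r in scan:
            by_id.setdefault(r.variant_id, []).append(r)
    return [ivw_meta(rs) for rs in by_id.values()]


# ---------------------------------------------------------------------------
# Clumping and locus definition
# ---------------------------------------------------------------------------

def clump_and_define_loci(
    meta: pd.DataFrame,
    ld_r2: pd.DataFrame,
    p1: float = GW_THRESHOLD,
    p2: float = 0.05,
    r2: float = 0.1,
    kb: float = 10_000,
    locus_flank_kb: float = 500,
) -> list[Locus]:
    """Two-round greedy clumping, then +-flank loci around surviving indices.

    Round 1 mirrors PLINK ``--clump-p1 5e-8 --clump-p2 0.05 --clump-r2 0.1
    --clump-kb 10000``; round 2 re-clumps the round-1 index variants with any
    nonzero LD inside a 500 kb window; each final locus spans
    ``index pos +- locus_flank_kb``.

    ``meta`` needs columns variant_id, chrom, pos, p; ``ld_r2`` is a square
    DataFrame indexed by variant id.
    """
    df = meta.sort_values(["p", "variant_id"]).reset_index(drop=True)
    assigned: set[str] = set()
    clumps: list[tuple[str, list[str]]] = []
    info = df.set_index("variant_id")
    for _, row in df.iterrows():
        vid = row["variant_id"]
        if vid in assigned or row["p"] >= p1:
            continue
        members = [vid]
        assigned.add(vid)
        for _, cand in df.iterrows():
            cid = cand["variant_id"]
            if cid in assigned or cand["p"] >= p2 or cand["chrom"] != row["chrom"]:
                continue
            if abs(cand["pos"] - row["pos"]) > kb * 1000:
                continue
            if cid in ld_r2.index and vid in ld_r2.columns and ld_r2.loc[vid, cid] > r2:
                members.append(cid)
                assigned.add(cid)
        clumps.append((vid, members))

    # round 2: merge round-1 indices with any LD within the flank window
    indices = [c[0] for c in clumps]
    merged: dict[str, list[str]] = {}
    taken: set[str] = set()
    order = sorted(indices, key=lambda v: (info.loc[v, "p"], v))
    clump_members = dict(clumps)
    for vid in order:
        if vid in taken:
            continue
        taken.add(vid)
        merged[vid] = list(clump_members[vid])
        for other in order:
            if other in taken or info.loc[other, "chrom"] != info.loc[vid, "chrom"]:
                continue
            close = abs(info.loc[other, "pos"] - info.loc[vid, "pos"]) <= locus_flank_kb * 1000
            linked = (
                other in ld_r2.index and vid in ld_r2.columns and ld_r2.loc[vid, other] > 0
            )
            if close and linked:
                taken.add(other)
                merged[vid].extend(clump_members[other])

    flank = int(locus_flank_kb * 1000)
    return [
        Locus(
            index_id=vid,
            chrom=str(info.loc[vid, "chrom"]),
            start=max(1, int(info.loc[vid, "pos"]) - flank),
            end=int(info.loc[vid, "pos"]) + flank,
            members=tuple(members),
        )
        for vid, members in merged.items()
    ]


# ---------------------------------------------------------------------------
# Stepwise conditional analysis
# ---------------------------------------------------------------------------

def build_precondition_covariates(
    G: np.ndarray,
    variant_ids: list[str],
    alleles: list[str],
    interactions: list[tuple[str, str]],
) -> pd.DataFrame:
    """Preconditioning design: one dosage column per risk-allele tag plus one
    binary column per interaction pair (1 iff the individual carries at least
    one copy of both members). Column count is ``len(alleles) +
    len(interactions)``."""
    idx = {v: j for j, v in enumerate(variant_ids)}
    data: dict[str, np.ndarray] = {}
    for a in alleles:
        if a not in idx:
            raise KeyError(f"unknown allele tag: {a}")
        data[a] = G[:, idx[a]].astype(float)
    for a, b in interactions:
        for t in (a, b):
            if t not in idx:
                raise KeyError(f"unknown interaction member: {t}")
        data[f"{a}:{b}"] = ((G[:, idx[a]] > 0) & (G[:, idx[b]] > 0)).astype(float)
    return pd.DataFrame(data)


def stepwise_conditional(
    cohorts: list[tuple[np.ndarray, np.ndarray]],
    variant_ids: list[str],
    base_covars: list[pd.DataFrame | None] | None = None,
    threshold: float = GW_THRESHOLD,
    max_signals: int = 20,
) -> list[ConditionalSignal]:
    """Iterative conditional signal discovery across cohorts.

    Each round runs Firth association for every remaining variant in every
    cohort with the current conditioning set (dosages of previously selected
    leads) added to the covariates, meta-analyzes, and promotes the most
    significant variant; stops when the minimum meta p-value reaches the
    threshold. Ties break by smallest p, then largest |z|, then variant id.
    Variants collinear with the conditioning set are skipped with a warning.
    """
    if not variant_ids:
        raise ValueError("region is empty")
    if base_covars is None:
        base_covars = [None] * len(cohorts)
    idx = {v: j for j, v in enumerate(variant_ids)}
    conditioning: list[str] = []
    signals: list[ConditionalSignal] = []
    remaining = list(variant_ids)

    while len(signals) < max_signals and remaining:
        metas: list[MetaResult] = []
        for vid in remaining:
            per_cohort: list[AssocResult] = []
            ok = True
            for (y, G), bc in zip(cohorts, base_covars):
                parts = []
                if bc is not None:
                    parts.append(bc.to_numpy(dtype=float) if isinstance(bc, pd.DataFrame) else bc)
                if conditioning:
                    parts.append(np.column_stack([G[:, idx[c]] for c in conditioning]).astype(float))
                covars = np.column_stack(parts) if parts else None
                try:
                    per_cohort.append(
                        firth_logistic(y, G[:, idx[vid]], covars=covars, variant_id=vid)
                    )
                except ValueError as e:
                    warnings.warn(f"skipping {vid}: {e}", stacklevel=2)
                    ok = False
                    break
            if ok and per_cohort:
                metas.append(ivw_meta(per_cohort))
        if not metas:
            break
        metas.sort(key=lambda m: (m.p, -abs(m.z), m.variant_id))
        best = metas[0]
        if best.p >= threshold:
            break
        signals.append(
            ConditionalSignal(
                rank=len(signals) + 1, lead=best.variant_id, beta=best.beta,
                se=best.se, p=best.p, conditioning_set=tuple(conditioning),
            )
        )
        conditioning.append(best.variant_id)
        remaining.remove(best.variant_id)
    return signals


def assoc_results_to_frame(results: list[AssocResult | MetaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variant_id": r.variant_id, "beta": r.beta, "se": r.se,
                "z": r.z, "p": r.p,
                "n": getattr(r, "n", getattr(r, "n_total", np.nan)),
                "af": getattr(r, "af", np.nan),
            }
        )
    return pd.DataFrame(rows)
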