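"""CNV association testing against estimated breeding values (EBVs).

Each retained CNV event is tested one at a time in the additive model

    y_i = a + sum_c PC_ic g_c + x_ij b_j + e_i

where y_i is the sample's EBV for one trait, x_ij in {0, 1, 2} is its
copy-number dose at event j, and the leading principal components of the
genotype matrix absorb population stratification.  Significance comes from
Freedman-Lane permutations: the phenotype is residualized on the
covariates, residuals are permuted, and the full-model t-statistic for
x_j is recomputed under each permutation.  Per trait, permutation
p-values are Benjamini-Hochberg adjusted and events with q < alpha are
declared significant.

The model is exposed statsmodels-style: build a :class:`CnvGwas` from a
genotype matrix, a phenotype and PC scores, call :meth:`CnvGwas.fit`, and
read estimates and diagnostics off the returned :class:`CnvGwasResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Trait table

class TraitTable:
    """Per-sample EBVs with accuracies for a set of traits.

    Backed by a DataFrame indexed by sample_id with columns
    ``<trait>_ebv`` and ``<trait>_acc``.  The accuracy of an EBV (square
    root of reliability) gates sample inclusion per trait.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" in frame.columns:
                frame = frame.set_index("sample_id")
            else:
                frame.index.name = "sample_id"
        self.frame = frame
        self.trait_names = sorted({c[:-4] for c in frame.columns if c.endswith("_ebv")})
        for t in self.trait_names:
            if f"{t}_acc" not in frame.columns:
                raise ValueError(f"trait {t} has EBVs but no accuracy column")
            acc = frame[f"{t}_acc"]
            if ((acc < 0) | (acc > 1)).any():
                raise ValueError(f"accuracy outside [0, 1] for trait {t}")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def ebv(self, trait: str) -> pd.Series:
        return self.frame[f"{trait}_ebv"]

    def accuracy(self, trait: str) -> pd.Series:
        return self.frame[f"{trait}_acc"]

    @classmethod
    def read(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def filter_by_accuracy(traits: TraitTable, trait: str,
                       min_accuracy: float = 0.5) -> pd.Index:
    """Samples with accuracy strictly above the threshold and a non-missing EBV."""
    if trait not in traits.trait_names:
        raise KeyError(f"unknown trait {trait!r}; have {traits.trait_names}")
    acc = traits.accuracy(trait)
    ebv = traits.ebv(trait)
    keep = (acc > min_accuracy) & ebv.notna()
    idx = traits.frame.index[keep]
    if len(idx) == 0:
        raise ValueError(
            f"no samples pass accuracy > {min_accuracy} for trait {trait!r}")
    return idx


def trait_correlations(traits: TraitTable, complete_cases_only: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlations between trait EBVs (complete cases)."""
    ebv = traits.frame[[f"{t}_ebv" for t in traits.trait_names]]
    ebv.columns = traits.trait_names
    if complete_cases_only:
        ebv = ebv.dropna()
    if len(ebv) < 3:
        raise ValueError("need at least 3 complete-case samples")
    constant = [t for t in ebv.columns if ebv[t].nunique() <= 1]
    if constant:
        log.warning("zero-variance traits, correlations undefined: %s", constant)
    return ebv.corr(method="pearson")


# ---------------------------------------------------------------------------
# Principal components

def compute_pcs(genotypes: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k PC scores of the centered, unit-scaled genotype matrix.

    Zero-variance events are dropped with a warning.  Scores are left
    singular vectors scaled by singular values, with the deterministic sign
    convention that each component's largest-magnitude loading is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = genotypes.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(genotypes.columns[~keep])
        log.warning("dropping %d zero-variance events before PCA: %s",
                    len(dropped), dropped[:5])
    X = X[:, keep]
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(n_samples, n_events)={min(X.shape)}")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(scores, index=genotypes.index,
                        columns=[f"PC{j + 1}" for j in range(k)])


# ---------------------------------------------------------------------------
# FDR

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# The GWAS model

class CnvGwas:
    """Per-event additive association model with PC covariates.

    Parameters
    ----------
    genotypes : DataFrame, samples x events, dose in {0, 1, 2}
    phenotype : Series of EBVs aligned (or alignable) to the genotypes
    pcs : DataFrame of PC scores or None for intercept-only covariates
    """

    def __init__(self, genotypes: pd.DataFrame, phenotype: pd.Series,
                 pcs: pd.DataFrame | None = None):
        common = genotypes.index.intersection(phenotype.dropna().index)
        if pcs is not None:
            common = common.intersection(pcs.index)
        if len(common) < 3:
            raise ValueError("fewer than 3 samples shared by genotypes/phenotype/PCs")
        common = genotypes.index[genotypes.index.isin(common)]  # keep genotype order
        self.genotypes = genotypes.loc[common]
        self.phenotype = phenotype.loc[common].astype(float)
        self.pcs = pcs.loc[common] if pcs is not None else None
        self.nobs = len(common)

        Z = np.ones((self.nobs, 1))
        if self.pcs is not None:
            Z = np.column_stack([Z, self.pcs.to_numpy(dtype=float)])
        # collinearity among covariates is a hard error, named by column
        q, r = np.linalg.qr(Z)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        if len(bad):
            names = ["intercept"] + (list(self.pcs.columns) if self.pcs is not None else [])
            raise ValueError(f"collinear covariate columns: {[names[i] for i in bad]}")
        self._Q = q
        self._n_covar = Z.shape[1]

    def _residualize(self, V: np.ndarray) -> np.ndarray:
        return V - self._Q @ (self._Q.T @ V)

    def fit(self, n_permutations: int = 10000, seed: int | None = None,
            alpha: float = 0.05, block_size: int = 512) -> "CnvGwasResults":
        if n_permutations < 100:
            raise ValueError("use at least 100 permutations")
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        n = self.nobs
        df = n - self._n_covar - 1
        if df < 1:
            raise ValueError("not enough residual degrees of freedom")

        X = self.genotypes.to_numpy(dtype=float)
        y = self.phenotype.to_numpy(dtype=float)
        e = self._residualize(y[:, None])[:, 0]
        ee = float(e @ e)

        Xr = self._residualize(X)
        xnorm2 = (Xr ** 2).sum(axis=0)
        col_sd = X.std(axis=0)
        # zero-variance or covariate-collinear events get flagged records
        valid = (col_sd > 0) & (xnorm2 > 1e-12 * n)

        beta = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
        tval = np.full(X.shape[1], np.nan)
        xty = Xr.T @ e
        with np.errstate(divide="ignore", invalid="ignore"):
            b = xty / xnorm2
            rss = ee - xty ** 2 / xnorm2
            s2 = rss / df
            sev = np.sqrt(s2 / xnorm2)
        beta[valid] = b[valid]
        se[valid] = sev[valid]
        tval[valid] = (b / sev)[valid]
        p_asym = np.where(np.isfinite(tval),
                          2.0 * stats.t.sf(np.abs(tval), df), np.nan)

        # Freedman-Lane: permute covariate residuals, re-residualize, refit
        rng = np.random.default_rng(seed)
        abs_t = np.abs(np.where(valid, tval, np.inf))
        counts = np.zeros(X.shape[1], dtype=np.int64)
        xnorm = np.sqrt(np.where(valid, xnorm2, 1.0))
        done = 0
        while done < n_permutations:
            b_this = min(block_size, n_permutations - done)
            perm = np.empty((n, b_this), dtype=float)
            for c in range(b_this):
                perm[:, c] = e[rng.permutation(n)]
            E = self._residualize(perm)
            enorm = np.sqrt((E ** 2).sum(axis=0))
            enorm[enorm == 0] = 1.0
            R = (Xr.T @ E) / (xnorm[:, None] * enorm[None, :])
            np.clip(R, -1.0, 1.0, out=R)
            with np.errstate(divide="ignore", invalid="ignore"):
                T = R * np.sqrt(df / np.maximum(1.0 - R ** 2, 1e-300))
            counts += (np.abs(T) >= abs_t[:, None]).sum(axis=1)
            done += b_this
        p_perm = np.where(valid, (1.0 + counts) / (1.0 + n_permutations), np.nan)

        q = np.full(X.shape[1], np.nan)
        if valid.any():
            q[valid] = fdr_adjust(p_perm[valid])
        frame = pd.DataFrame({
            "cnv": list(self.genotypes.columns),
            "beta_hat": beta,
            "se": se,
            "t_stat": tval,
            "p_perm": p_perm,
            "p_asym": p_asym,
            "q_fdr": q,
            "n_used": n,
            "zero_variance": ~valid,
        })
        frame["significant"] = frame["q_fdr"] < alpha
        return CnvGwasResults(frame=frame, alpha=alpha,
                              n_permutations=n_permutations, nobs=n,
                              n_covariates=self._n_covar)


@dataclass
class CnvGwasResults:
    """Association estimates, permutation p-values and FDR q-values."""

    frame: pd.DataFrame
    alpha: float
    n_permutations: int
    nobs: int
    n_covariates: int

    def significant_cnvs(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "cnv"].tolist()

    def record(self, cnv: str) -> pd.Series:
        hit = self.frame[self.frame["cnv"] == cnv]
        if hit.empty:
            raise KeyError(cnv)
        return hit.iloc[0]

    def summary(self, max_rows: int = 20) -> str:
        sig = int(self.frame["significant"].sum())
        head = (
            f"CNV association results  (n={self.nobs}, "
            f"{self.n_covariates - 1} PCs, {self.n_permutations} permutations)\n"
            f"events tested: {len(self.frame)}   "
            f"significant at FDR q < {self.alpha}: {sig}\n"
        )
        cols = ["cnv", "beta_hat", "se", "t_stat", "p_perm", "q_fdr", "significant"]
        body = (self.frame.sort_values("q_fdr")[cols]
                .head(max_rows)
                .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return head + body

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def associate(genotypes: pd.DataFrame, traits: TraitTable, trait: str,
              pcs: pd.DataFrame | None, n_permutations: int, seed: int | None,
              alpha: float = 0.05, min_accuracy: float | None = None) -> CnvGwasResults:
    """Functional wrapper: accuracy-gate samples, fit the model for one trait."""
    y = traits.ebv(trait)
    if min_accuracy is not None:
        idx = filter_by_accuracy(traits, trait, min_accuracy)
        y = y.loc[idx]
    model = CnvGwas(genotypes, y, pcs)
    return model.fit(n_permutations=n_permutations, seed=seed, alpha=alpha)


def manhattan_table(results: CnvGwasResults, events) -> pd.DataFrame:
    """Per-event (chromosome, midpoint, -log10 p) table for plotting."""
    pos = {e.name: (e.chromosome, (e.start_bp + e.end_bp) // 2) for e in events}
    rows = []
    for _, r in results.frame.iterrows():
        chrom, mid = pos.get(r["cnv"], ("?", np.nan))
        rows.append((r["cnv"], chrom, mid,
                     -np.log10(r["p_perm"]) if np.isfinite(r["p_perm"]) else np.nan))
    return pd.DataFrame(rows, columns=["cnv", "chromosome", "position_bp",
                                       "minus_log10_p"])
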