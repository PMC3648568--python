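"""Marker-based QTL scans with empirical permutation thresholds.

The model is a Haley-Knott-style regression approximation: at observed
markers the phenotype is regressed on the additive genotype code, and at
pseudomarkers on the expected donor dose given flanking markers under
Haldane's map function.  LOD = (n/2) log10(RSS0/RSS1); genome-wide
significance comes from the (1 - alpha) quantile of max-LOD over phenotype
permutations.  A cofactor-augmented (composite) scan forward-selects marker
covariates and drops them within a window around the test position.

Regression replaces EM mixture maximum likelihood deliberately: at the
near-complete homozygosity of backcross-inbred lines the two are practically
indistinguishable, and the regression form is deterministic and
closed-form-checkable.

The scan is exposed statsmodels-style: build a :class:`QTLScan` model from
phenotype + genotypes + map, call :meth:`QTLScan.fit`, and read the
:class:`QTLScanResults` profile/peaks/summary.  The module-level functions
(:func:`single_marker_scan`, :func:`interval_scan`, :func:`composite_scan`,
:func:`permutation_threshold`) are thin wrappers over the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import chromosome_sort_key

__all__ = [
    "QTLScan",
    "QTLScanResults",
    "single_marker_scan",
    "interval_scan",
    "composite_scan",
    "permutation_threshold",
]

_RSS_FLOOR = 1e-12  # floor on RSS1/RSS0; caps LOD in perfect-fit degeneracies


def _haldane_recomb(d_cm: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _validate_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    required = {"marker_id", "chromosome", "position_bp", "position_cM"}
    missing = required - set(marker_map.columns)
    if missing:
        raise ValueError(f"marker map lacks columns: {sorted(missing)}")
    mm = marker_map.sort_values(
        ["chromosome", "position_cM"],
        key=lambda s: s.map(chromosome_sort_key) if s.name == "chromosome" else s,
    ).reset_index(drop=True)
    for chrom, grp in mm.groupby("chromosome", sort=False):
        pos = grp["position_cM"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: marker positions must be strictly increasing")
    return mm


class QTLScan:
    """Single-population QTL scan model.

    Parameters
    ----------
    genotypes : DataFrame, individuals x markers
        Additive codes 0 (recurrent homozygote), 1 (heterozygote),
        2 (donor homozygote); NaN marks missing.
    phenotype : Series or array, one value per individual (kg/ha)
    marker_map : DataFrame with marker_id, chromosome, position_bp, position_cM
    """

    def __init__(self, genotypes: pd.DataFrame, phenotype, marker_map: pd.DataFrame):
        self.marker_map = _validate_map(marker_map)
        order = self.marker_map["marker_id"].tolist()
        missing_cols = [m for m in order if m not in genotypes.columns]
        if missing_cols:
            raise ValueError(f"genotypes lack mapped markers: {missing_cols[:5]} ...")
        self.genotypes = genotypes[order]
        y = np.asarray(
            phenotype.to_numpy() if hasattr(phenotype, "to_numpy") else phenotype,
            dtype=float,
        )
        if y.shape[0] != self.genotypes.shape[0]:
            raise ValueError("phenotype length does not match genotype rows")
        if y.shape[0] < 30:
            raise ValueError("scan requires n >= 30 individuals")
        self.phenotype = y
        codes = self.genotypes.to_numpy(dtype=float)
        valid = np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be in {0, 1, 2} or missing")
        self._X = codes
        self.n_obs = y.shape[0]

    # -- helpers ----------------------------------------------------------

    def _marker_stats(self, X: np.ndarray, y: np.ndarray):
        """Vectorized per-column regression with pairwise deletion.

        Returns (n_k, lod, r2, slope) arrays over columns of X.
        """
        M = ~np.isnan(X)
        Xf = np.where(M, X, 0.0)
        n_k = M.sum(axis=0).astype(float)
        Sx = Xf.sum(axis=0)
        Sxx_raw = (Xf**2).sum(axis=0)
        Sy = M.T @ y
        Syy_raw = M.T @ (y**2)
        Sxy_raw = Xf.T @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            Sxx = Sxx_raw - Sx**2 / n_k
            Syy = Syy_raw - Sy**2 / n_k
            Sxy = Sxy_raw - Sx * Sy / n_k
            r2 = np.where((Sxx > 0) & (Syy > 0), Sxy**2 / (Sxx * Syy), 0.0)
            slope = np.where(Sxx > 0, Sxy / np.where(Sxx > 0, Sxx, 1.0), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - _RSS_FLOOR)
        lod = -(n_k / 2.0) * np.log10(1.0 - r2)
        return n_k, lod, r2, slope

    def _imputed_doses(self) -> np.ndarray:
        """Marker donor doses (codes) with missing entries imputed from flanks."""
        X = self._X.copy()
        mm = self.marker_map
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
        for chrom, grp in mm.groupby("chromosome", sort=False):
            idx = grp.index.to_numpy()
            cm = grp["position_cM"].to_numpy()
            for j_local, j in enumerate(idx):
                miss = np.isnan(X[:, j])
                if not miss.any():
                    continue
                pL = pR = None
                rL = rR = None
                if j_local > 0:
                    jl = idx[j_local - 1]
                    pL = np.where(np.isnan(X[miss, jl]), col_mean[jl], X[miss, jl]) / 2.0
                    rL = _haldane_recomb(cm[j_local] - cm[j_local - 1])
                if j_local < len(idx) - 1:
                    jr = idx[j_local + 1]
                    pR = np.where(np.isnan(X[miss, jr]), col_mean[jr], X[miss, jr]) / 2.0
                    rR = _haldane_recomb(cm[j_local + 1] - cm[j_local])
                X[miss, j] = _conditional_dose(pL, rL, pR, rR, len(np.flatnonzero(miss)))
        return X

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "interval",
        step_cM: float = 1.0,
        n_cofactors: int = 0,
        window_cM: float = 10.0,
        n_perm: int | None = None,
        alpha: float = 0.01,
        perm_seed: int = 0,
    ) -> "QTLScanResults":
        """Run the scan and return a results object.

        method : {"single_marker", "interval", "composite"}
        n_perm : if given, also compute the genome-wide permutation
            threshold at ``alpha`` with ``perm_seed``.
        """
        if method == "single_marker":
            profile = self._fit_single_marker()
        elif method == "interval":
            profile = self._fit_grid(step_cM, cofactors=[], window_cM=window_cM)
        elif method == "composite":
            cof = self._select_cofactors(n_cofactors)
            profile = self._fit_grid(step_cM, cofactors=cof, window_cM=window_cM)
        else:
            raise ValueError(f"unknown scan method: {method!r}")
        results = QTLScanResults(
            profile=profile,
            method=method,
            n_obs=self.n_obs,
            marker_map=self.marker_map,
            model=self,
        )
        if n_perm is not None:
            results.threshold_lod = self.permutation_threshold(
                n_perm=n_perm, alpha=alpha, seed=perm_seed
            )
            results.n_permutations = n_perm
            results.alpha = alpha
        return results

    def _fit_single_marker(self) -> pd.DataFrame:
        X, y = self._X, self.phenotype
        n_k, lod, r2, slope = self._marker_stats(X, y)
        if np.any((np.nanmax(np.where(np.isnan(X), -np.inf, X), axis=0)
                   == np.nanmin(np.where(np.isnan(X), np.inf, X), axis=0))):
            warnings.warn("monomorphic marker(s): LOD recorded as 0", stacklevel=3)
        # additive effect: half the difference between homozygote class means
        additive = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            xj = X[:, j]
            hi = xj == 2.0
            lo = xj == 0.0
            if hi.any() and lo.any():
                additive[j] = (y[hi].mean() - y[lo].mean()) / 2.0
            else:
                additive[j] = slope[j]
        mm = self.marker_map
        return pd.DataFrame(
            {
                "chromosome": mm["chromosome"],
                "position_cM": mm["position_cM"],
                "position_bp": mm["position_bp"],
                "marker_id": mm["marker_id"],
                "LOD": lod,
                "r_squared": r2,
                "additive_effect": additive,
                "n": n_k.astype(int),
            }
        )

    def _grid(self, step_cM: float):
        """(chromosome, grid cM, grid bp, nearest marker id, dose matrix) tuples."""
        if step_cM <= 0:
            raise ValueError("step_cM must be positive")
        Ximp = self._imputed_doses()
        out = []
        for chrom, grp in self.marker_map.groupby("chromosome", sort=False):
            idx = grp.index.to_numpy()
            cm = grp["position_cM"].to_numpy()
            bp = grp["position_bp"].to_numpy().astype(float)
            ids = grp["marker_id"].to_numpy()
            grid = np.union1d(np.arange(cm[0], cm[-1], step_cM), cm)
            doses = np.empty((self.n_obs, len(grid)))
            nearest = []
            gbp = np.interp(grid, cm, bp)
            for k, g in enumerate(grid):
                j = int(np.searchsorted(cm, g))
                if j < len(cm) and np.isclose(cm[j], g):
                    doses[:, k] = Ximp[:, idx[j]]
                    nearest.append(ids[j])
                    continue
                jl, jr = j - 1, j
                pL = Ximp[:, idx[jl]] / 2.0
                rL = _haldane_recomb(g - cm[jl])
                pR = Ximp[:, idx[jr]] / 2.0
                rR = _haldane_recomb(cm[jr] - g)
                doses[:, k] = _conditional_dose(pL, rL, pR, rR, self.n_obs)
                nearest.append(ids[jl] if (g - cm[jl]) <= (cm[jr] - g) else ids[jr])
            out.append((chrom, grid, gbp, nearest, doses))
        return out

    def _fit_grid(
        self, step_cM: float, cofactors: list[int], window_cM: float
    ) -> pd.DataFrame:
        y = self.phenotype
        yc = y - y.mean()
        rows = []
        mm = self.marker_map
        cof_chrom = mm["chromosome"].to_numpy()
        cof_cm = mm["position_cM"].to_numpy()
        Ximp = self._imputed_doses() if cofactors else None
        for chrom, grid, gbp, nearest, doses in self._grid(step_cM):
            if not cofactors:
                n_k, lod, r2, slope = self._marker_stats(doses, y)
                for k in range(len(grid)):
                    rows.append(
                        (chrom, grid[k], gbp[k], nearest[k], lod[k], r2[k], slope[k],
                         self.n_obs)
                    )
                continue
            for k in range(len(grid)):
                keep = [
                    j
                    for j in cofactors
                    if not (
                        cof_chrom[j] == chrom and abs(cof_cm[j] - grid[k]) < window_cM
                    )
                ]
                C = Ximp[:, keep] if keep else np.empty((self.n_obs, 0))
                Cc = C - C.mean(axis=0) if C.size else C
                x = doses[:, k]
                xc = x - x.mean()
                red = np.column_stack([Cc]) if Cc.size else np.empty((self.n_obs, 0))
                full = np.column_stack([red, xc]) if red.size else xc[:, None]
                rss_red = _rss(red, yc)
                rss_full = _rss(full, yc)
                rss_full = max(rss_full, _RSS_FLOOR * max(rss_red, 1e-300))
                lod = (self.n_obs / 2.0) * np.log10(rss_red / rss_full)
                r2 = 1.0 - rss_full / rss_red if rss_red > 0 else 0.0
                coef, *_ = np.linalg.lstsq(full, yc, rcond=None)
                rows.append(
                    (chrom, grid[k], gbp[k], nearest[k], lod, r2, coef[-1], self.n_obs)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome",
                "position_cM",
                "position_bp",
                "marker_id",
                "LOD",
                "r_squared",
                "additive_effect",
                "n",
            ],
        )

    def _select_cofactors(self, n_cofactors: int) -> list[int]:
        """Forward selection of marker cofactors by residual correlation."""
        if n_cofactors == 0:
            return []
        if n_cofactors >= self.n_obs / 10:
            raise ValueError("n_cofactors must be < n/10")
        Ximp = self._imputed_doses()
        Xc = Ximp - Ximp.mean(axis=0)
        norms = np.sqrt((Xc**2).sum(axis=0))
        y = self.phenotype - self.phenotype.mean()
        selected: list[int] = []
        dropped = 0
        resid = y.copy()
        while len(selected) < n_cofactors:
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.abs(Xc.T @ resid) / np.where(norms > 0, norms, np.inf)
            scores[selected] = -np.inf
            order = np.argsort(scores)[::-1]
            picked = None
            for j in order:
                if scores[j] <= 0 or not np.isfinite(scores[j]):
                    break
                # skip near-collinear candidates
                if selected:
                    S = Xc[:, selected]
                    cors = np.abs(
                        (S.T @ Xc[:, j]) / (norms[selected] * norms[j] + 1e-300)
                    )
                    if np.any(cors > 0.999):
                        scores[j] = -np.inf
                        dropped += 1
                        continue
                picked = int(j)
                break
            if picked is None:
                break
            selected.append(picked)
            design = np.column_stack([Xc[:, selected]])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
        if dropped:
            warnings.warn(f"dropped {dropped} collinear cofactor candidate(s)",
                          stacklevel=3)
        return selected

    def permutation_threshold(
        self, n_perm: int = 1_000, alpha: float = 0.01, seed: int = 0
    ) -> float:
        """(1 - alpha) quantile of genome-wide max LOD over phenotype permutations.

        The scan under permutation is the single-marker regression on
        mean-imputed genotypes (vectorized over all permutations);
        deterministic under a fixed seed.
        """
        if n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        rng = np.random.default_rng(seed)
        X = self._X
        col_mean = np.nanmean(X, axis=0)
        Xi = np.where(np.isnan(X), col_mean, X)
        Xc = Xi - Xi.mean(axis=0)
        Sxx = (Xc**2).sum(axis=0)
        ok = Sxx > 0
        Xc = Xc[:, ok]
        Sxx = Sxx[ok]
        y = self.phenotype
        Y = np.empty((self.n_obs, n_perm))
        for b in range(n_perm):
            Y[:, b] = rng.permutation(y)
        Yc = Y - Y.mean(axis=0)
        Syy = (Yc**2).sum(axis=0)
        Sxy = Xc.T @ Yc  # markers x perms
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = Sxy**2 / (Sxx[:, None] * Syy[None, :])
        r2 = np.clip(r2, 0.0, 1.0 - _RSS_FLOOR)
        maxlod = (-(self.n_obs / 2.0) * np.log10(1.0 - r2)).max(axis=0)
        return float(np.quantile(maxlod, 1.0 - alpha, method="higher"))


def _conditional_dose(pL, rL, pR, rR, n: int) -> np.ndarray:
    """Expected donor dose given flanking donor probabilities.

    Two-state conditioning: each flank contributes the probability that the
    chromatid state carries through given the Haldane recombination fraction
    to the test position.  A missing flank (chromosome end) drops out.
    """
    tB = np.ones(n)
    tA = np.ones(n)
    if pL is not None:
        tB = tB * (pL * (1.0 - rL) + (1.0 - pL) * rL)
        tA = tA * (pL * rL + (1.0 - pL) * (1.0 - rL))
    if pR is not None:
        tB = tB * (pR * (1.0 - rR) + (1.0 - pR) * rR)
        tA = tA * (pR * rR + (1.0 - pR) * (1.0 - rR))
    denom = tA + tB
    pB = np.where(denom > 0, tB / np.where(denom > 0, denom, 1.0), 0.5)
    return 2.0 * pB


def _rss(design: np.ndarray, yc: np.ndarray) -> float:
    if design.size == 0:
        return float(yc @ yc)
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    resid = yc - design @ coef
    return float(resid @ resid)


@dataclass
class QTLScanResults:
    """Scan profile with peak extraction, summary table and plotting."""

    profile: pd.DataFrame
    method: str
    n_obs: int
    marker_map: pd.DataFrame
    model: QTLScan | None = None
    threshold_lod: float | None = None
    n_permutations: int | None = None
    alpha: float | None = None

    def peaks(self, threshold_lod: float | None = None) -> pd.DataFrame:
        """Per-chromosome LOD peaks (ties broken toward the smaller coordinate).

        With a threshold (argument or stored permutation threshold), only
        peaks at or above it are reported, each with its flanking marker
        interval and nearest (peak) marker.
        """
        thr = threshold_lod if threshold_lod is not None else self.threshold_lod
        rows = []
        for chrom, grp in self.profile.groupby("chromosome", sort=False):
            grp = grp.sort_values("position_cM")
            k = int(np.argmax(grp["LOD"].to_numpy()))
            row = grp.iloc[k]
            if thr is not None and row["LOD"] < thr:
                continue
            mm = self.marker_map[self.marker_map["chromosome"] == chrom]
            cm = mm["position_cM"].to_numpy()
            ids = mm["marker_id"].to_numpy()
            left = ids[max(0, int(np.searchsorted(cm, row["position_cM"], "right")) - 1)]
            right = ids[min(len(ids) - 1, int(np.searchsorted(cm, row["position_cM"], "left")))]
            interval = left if left == right else f"{left}-{right}"
            rows.append(
                {
                    "chromosome": chrom,
                    "marker_interval": interval,
                    "peak_marker": row["marker_id"],
                    "position_cM": row["position_cM"],
                    "position_bp": row["position_bp"],
                    "LOD": row["LOD"],
                    "r_squared": row["r_squared"],
                    "additive_effect": row["additive_effect"],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome",
                "marker_interval",
                "peak_marker",
                "position_cM",
                "position_bp",
                "LOD",
                "r_squared",
                "additive_effect",
            ],
        )

    def summary(self) -> str:
        """Text summary mirroring the standard scan-report layout."""
        peaks = self.peaks()
        lines = [
            f"QTL scan ({self.method}), n = {self.n_obs}",
        ]
        if self.threshold_lod is not None:
            lines.append(
                f"permutation threshold: LOD {self.threshold_lod:.2f} "
                f"(alpha={self.alpha}, {self.n_permutations} permutations)"
            )
        lines.append("")
        with pd.option_context("display.width", 120):
            lines.append(
                peaks.to_string(
                    index=False,
                    formatters={
                        "LOD": "{:.2f}".format,
                        "r_squared": "{:.3f}".format,
                        "additive_effect": "{:.1f}".format,
                        "position_cM": "{:.1f}".format,
                    },
                )
                if len(peaks)
                else "no peaks above threshold"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile by chromosome; draws the threshold line when present."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks, labels = [], []
        for chrom, grp in self.profile.groupby("chromosome", sort=False):
            grp = grp.sort_values("position_cM")
            x = grp["position_cM"].to_numpy() + offset
            ax.plot(x, grp["LOD"], lw=1)
            ticks.append(offset + grp["position_cM"].mean())
            labels.append(chrom)
            offset = x[-1] + 5
        if self.threshold_lod is not None:
            ax.axhline(self.threshold_lod, ls="--", color="grey", lw=0.8)
        ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
        ax.set_ylabel("LOD")
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def single_marker_scan(genotypes, phenotype, marker_map) -> QTLScanResults:
    """Per-marker regression scan (pairwise deletion of missing genotypes)."""
    return QTLScan(genotypes, phenotype, marker_map).fit(method="single_marker")


def interval_scan(genotypes, phenotype, marker_map, step_cM: float = 1.0) -> QTLScanResults:
    """Regression interval scan on expected doses at pseudomarkers."""
    return QTLScan(genotypes, phenotype, marker_map).fit(
        method="interval", step_cM=step_cM
    )


def composite_scan(
    genotypes, phenotype, marker_map, n_cofactors: int, step_cM: float = 1.0
) -> QTLScanResults:
    """Cofactor-augmented interval scan (composite interval mapping)."""
    return QTLScan(genotypes, phenotype, marker_map).fit(
        method="composite", step_cM=step_cM, n_cofactors=n_cofactors
    )


def permutation_threshold(
    genotypes, phenotype, marker_map, n_perm: int = 1_000, alpha: float = 0.01,
    seed: int = 0
) -> float:
    """Genome-wide LOD threshold from phenotype permutations."""
    return QTLScan(genotypes, phenotype, marker_map).permutation_threshold(
        n_perm=n_perm, alpha=alpha, seed=seed
    )
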