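"""Hill dose-response modelling with a shared maximal-inhibition plateau.

The inhibition of ACh-evoked currents by a modulator is described by the
Hill equation on the normalized current scale (% of control):

    response(D) = bottom + (top - bottom) / (1 + (D / IC50)^nH)

with top fixed at the control level (100%).  When the highest attainable
ligand concentration cannot define the plateau for every receptor
subtype, all datasets are fitted simultaneously with one *shared* bottom
(maximal-inhibition level) while IC50 and the Hill slope nH stay
per-dataset — the convention used for the α4β2/α3β2 receptor panel this
package models.

Usage follows the Model / Results idiom::

    model = HillModel(datasets)              # or HillModel.from_dataframe(df)
    res = model.fit()
    print(res.summary())
    lo, hi = res.bootstrap_ci(n_boot=200, seed=7)["ic50"]["HS a4b2"]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DoseResponseDataset:
    label: str
    doses: np.ndarray       # μM, > 0
    responses: np.ndarray   # % of control
    replicate_ids: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must align")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses must be finite")
        if len(np.unique(self.doses)) < 3:
            raise ValueError(f"dataset {self.label!r} needs >= 3 distinct doses")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)


def hill_response(dose, ic50: float, nh: float, bottom: float,
                  top: float = 100.0):
    """Normalized current (%) at a given dose (μM); decreasing for nh > 0."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** nh, 0.0)
    out = bottom + (top - bottom) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


class HillModel:
    """Simultaneous Hill fit over one or more dose-response datasets.

    Parameters: per-dataset (IC50, nH) plus one bottom plateau shared
    across datasets (``share_bottom=True``, default) or per-dataset;
    top is fixed (default 100% of control).
    """

    def __init__(self, datasets: list[DoseResponseDataset], top: float = 100.0,
                 share_bottom: bool = True):
        if not datasets:
            raise ValueError("need at least one dataset")
        self.datasets = list(datasets)
        self.top = float(top)
        self.share_bottom = bool(share_bottom)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       dose_col: str = "dose_uM",
                       response_col: str = "response_pct",
                       replicate_col: str | None = "replicate",
                       **kwargs) -> "HillModel":
        datasets = []
        for label, grp in df.groupby(label_col, sort=False):
            reps = None
            if replicate_col and replicate_col in grp:
                reps = grp[replicate_col].to_numpy()
            datasets.append(DoseResponseDataset(
                str(label), grp[dose_col].to_numpy(),
                grp[response_col].to_numpy(), reps))
        return cls(datasets, **kwargs)

    # -- internals ----------------------------------------------------------

    def _n_bottom(self) -> int:
        return 1 if self.share_bottom else len(self.datasets)

    def _unpack(self, theta: np.ndarray):
        k = len(self.datasets)
        log_ic50 = theta[:k]
        nh = theta[k : 2 * k]
        bottoms = theta[2 * k :]
        return np.exp(log_ic50), nh, bottoms

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        ic50, nh, bottoms = self._unpack(theta)
        out = []
        for i, ds in enumerate(self.datasets):
            b = bottoms[0] if self.share_bottom else bottoms[i]
            pred = hill_response(ds.doses, ic50[i], nh[i], b, self.top)
            out.append(pred - ds.responses)
        return np.concatenate(out)

    def fit(self, n_starts: int = 4) -> "HillFitResult":
        """Multi-start trust-region least squares.

        Starting IC50s are log-spaced over the pooled dose range; the
        start with the lowest final cost wins.  Non-convergence is
        flagged on the result rather than raised.
        """
        k = len(self.datasets)
        all_doses = np.concatenate([ds.doses for ds in self.datasets])
        lo, hi = all_doses.min(), all_doses.max()
        start_ic50 = np.geomspace(max(lo / 3, 1e-6), hi * 3, n_starts)
        resp_min = min(ds.responses.min() for ds in self.datasets)
        b0 = np.clip(resp_min, 0.0, self.top - 1e-6)

        nb = self._n_bottom()
        lb = np.concatenate([
            np.full(k, np.log(lo / 1e3)), np.full(k, 0.05),
            np.full(nb, min(0.0, resp_min - 50.0))])
        ub = np.concatenate([
            np.full(k, np.log(hi * 1e3)), np.full(k, 10.0),
            np.full(nb, self.top)])

        best = None
        cost_path: list[float] = []
        for s in start_ic50:
            theta0 = np.concatenate([
                np.full(k, np.log(s)), np.full(k, 1.0), np.full(nb, b0)])
            sol = least_squares(self._residuals, theta0, bounds=(lb, ub),
                                method="trf", x_scale="jac")
            cost_path.append(sol.cost)
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
        assert best is not None

        ic50, nh, bottoms = self._unpack(best.x)
        cov, bse = self._covariance(best)
        return HillFitResult(
            model=self, ic50=ic50, nh=nh,
            bottom=float(bottoms[0]) if self.share_bottom else bottoms,
            top=self.top, theta=best.x, cov=cov, bse=bse,
            cost=float(best.cost), converged=bool(best.success),
            start_costs=cost_path, message=best.message,
        )

    def _covariance(self, sol):
        m = len(sol.fun)
        p = len(sol.x)
        dof = max(m - p, 1)
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = np.full(p, np.nan)
        return cov, bse


@dataclass
class HillFitResult:
    """Estimates, uncertainties and diagnostics of a HillModel fit.

    ``ic50`` and ``nh`` are per-dataset arrays in dataset order; standard
    errors come from the asymptotic covariance (note the IC50 SE is
    propagated from the log-scale parameterization).
    """

    model: HillModel
    ic50: np.ndarray
    nh: np.ndarray
    bottom: float | np.ndarray
    top: float
    theta: np.ndarray
    cov: np.ndarray
    bse: np.ndarray
    cost: float
    converged: bool
    start_costs: list[float]
    message: str = ""

    @property
    def labels(self) -> list[str]:
        return [ds.label for ds in self.model.datasets]

    def ic50_se(self) -> np.ndarray:
        k = len(self.model.datasets)
        return self.bse[:k] * self.ic50  # delta method from log scale

    def nh_se(self) -> np.ndarray:
        k = len(self.model.datasets)
        return self.bse[k : 2 * k]

    def bottom_se(self):
        k = len(self.model.datasets)
        se = self.bse[2 * k :]
        return float(se[0]) if self.model.share_bottom else se

    def predict(self, label: str, doses) -> np.ndarray:
        i = self.labels.index(label)
        b = self.bottom if np.isscalar(self.bottom) else self.bottom[i]
        return hill_response(np.asarray(doses, dtype=float),
                             self.ic50[i], self.nh[i], b, self.top)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for i, label in enumerate(self.labels):
            b = self.bottom if np.isscalar(self.bottom) else self.bottom[i]
            rows.append({
                "label": label, "ic50_uM": self.ic50[i],
                "ic50_se": self.ic50_se()[i], "nH": self.nh[i],
                "nH_se": self.nh_se()[i], "bottom_pct": b,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.params_frame()
        lines = ["Hill fit (top fixed at %.1f%%; %s bottom)" % (
            self.top, "shared" if self.model.share_bottom else "per-dataset")]
        lines.append(f"converged: {self.converged}   cost: {self.cost:.4g}")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['label']:<12} IC50 = {r['ic50_uM']:7.2f} ± "
                f"{r['ic50_se']:.2f} μM   nH = {r['nH']:.2f} ± "
                f"{r['nH_se']:.2f}   bottom = {r['bottom_pct']:.1f}%"
            )
        if self.model.share_bottom:
            lines.append(f"  shared bottom SE = {self.bottom_se():.2f}")
        return "\n".join(lines)

    def bootstrap_ci(self, n_boot: int = 200, seed: int = 0,
                     alpha: float = 0.05) -> dict:
        """Percentile bootstrap over replicates (or points), seeded."""
        rng = np.random.default_rng(seed)
        draws = {"ic50": [], "nh": [], "bottom": []}
        for _ in range(n_boot):
            resampled = []
            for ds in self.model.datasets:
                if ds.replicate_ids is not None:
                    reps = np.unique(ds.replicate_ids)
                    pick = rng.choice(reps, size=len(reps), replace=True)
                    idx = np.concatenate(
                        [np.nonzero(ds.replicate_ids == r)[0] for r in pick])
                else:
                    idx = rng.integers(0, len(ds.doses), size=len(ds.doses))
                try:
                    resampled.append(DoseResponseDataset(
                        ds.label, ds.doses[idx], ds.responses[idx]))
                except ValueError:
                    resampled.append(ds)  # degenerate resample: keep original
            res = HillModel(resampled, self.top,
                            self.model.share_bottom).fit(n_starts=2)
            draws["ic50"].append(res.ic50)
            draws["nh"].append(res.nh)
            draws["bottom"].append(res.bottom)
        out: dict = {}
        q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        for name in ("ic50", "nh"):
            arr = np.asarray(draws[name])
            out[name] = {
                label: tuple(np.percentile(arr[:, i], q))
                for i, label in enumerate(self.labels)
            }
        barr = np.asarray(draws["bottom"])
        if barr.ndim == 1:
            out["bottom"] = tuple(np.percentile(barr, q))
        else:
            out["bottom"] = {
                label: tuple(np.percentile(barr[:, i], q))
                for i, label in enumerate(self.labels)
            }
        return out
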