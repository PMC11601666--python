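"""Model/Results interface over the full affinity-prediction pipeline.

:class:`PeptideAffinityModel` holds encoded peptides and log10(IC50 nM)
targets; ``fit()`` returns a :class:`PeptideAffinityResults` carrying the
fitted PLS coefficients, training diagnostics, cross-validation reports,
the component sweep and the comparator benchmark, plus a ``summary()``
table and scatter-ready prediction export.

Typical use::

    model = PeptideAffinityModel.from_export("filtered.csv")
    res = model.fit(n_components=3)
    print(res.summary())
    cv = res.cross_validation   # 5-fold held-out R^2 / RMSE
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chem_encoder, iedb_io, regression
from .chem_encoder import ReducerModel, TokenRegistry, default_registry
from .iedb_io import AffinityDataset, FilterConfig
from .notation import parse_epitope_name, tokenize

__all__ = ["PeptideAffinityModel", "PeptideAffinityResults"]


class PeptideAffinityModel:
    """Linear latent-variable model of peptide–MHC-I binding affinity.

    Parameters
    ----------
    names : sequence of str
        Epitope names in the ``SEQ + CODE(R#)`` notation.
    ic50_nm : sequence of float, optional
        IC50 values in nM; converted to log10 targets.  Give either this or
        ``targets``.
    targets : sequence of float, optional
        log10(IC50 nM) targets directly.
    registry : TokenRegistry, optional
        Token→SMILES registry; defaults to the packaged canonical-20 plus
        NCAA starter set.
    d, L_max : int
        Reduced per-residue dimension and maximum peptide length; the model
        input dimension is ``d * L_max`` (100 at the defaults).
    """

    def __init__(
        self,
        names,
        ic50_nm=None,
        targets=None,
        registry: TokenRegistry | None = None,
        d: int = 10,
        L_max: int = 10,
        reducer: ReducerModel | None = None,
        fit_on_dataset_tokens: bool = True,
    ):
        if (ic50_nm is None) == (targets is None):
            raise ValueError("give exactly one of ic50_nm or targets")
        if targets is None:
            targets = [iedb_io.to_target(v) for v in ic50_nm]
        self.names = list(names)
        if len(self.names) != len(targets):
            raise ValueError("names and targets length mismatch")
        self.registry = registry or default_registry()
        self.d = d
        self.L_max = L_max
        dataset = AffinityDataset(
            [iedb_io.AffinityRecord(name=n) for n in self.names],
            np.asarray(targets, dtype=float),
        )
        self.exog, self.endog, self.reducer, self.token_map = (
            chem_encoder.encode_dataset(
                dataset,
                self.registry,
                d=d,
                L_max=L_max,
                reducer=reducer,
                fit_on_dataset_tokens=fit_on_dataset_tokens,
            )
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_export(
        cls,
        path,
        filter_config: FilterConfig | None = None,
        registry: TokenRegistry | None = None,
        **kwargs,
    ) -> "PeptideAffinityModel":
        """Build from a raw IEDB-style export, applying the filter cascade."""
        dataset, report = iedb_io.build_dataset(path, filter_config)
        model = cls(
            [r.name for r in dataset.records],
            targets=dataset.targets,
            registry=registry,
            **kwargs,
        )
        model.filter_report = report
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        name_col: str = "Name",
        ic50_col: str = "Quantitative Measurement",
        registry: TokenRegistry | None = None,
        **kwargs,
    ) -> "PeptideAffinityModel":
        """Build from a pre-filtered DataFrame of names and IC50 values (nM)."""
        return cls(
            df[name_col].tolist(),
            ic50_nm=pd.to_numeric(df[ic50_col]).tolist(),
            registry=registry,
            **kwargs,
        )

    # ------------------------------------------------------------------ #
    @property
    def nobs(self) -> int:
        return len(self.names)

    def fit(
        self, n_components: int = 3, k: int = 5, seed: int = 0, cross_validate: bool = True
    ) -> "PeptideAffinityResults":
        """Fit PLS on all records; optionally run k-fold cross-validation."""
        pls = regression.fit_pls(self.exog, self.endog, n_components=n_components)
        cv = None
        oof = None
        if cross_validate:
            cv, oof = regression.cross_validate(
                self.exog,
                self.endog,
                k=k,
                seed=seed,
                model_factory=lambda X, y: regression.fit_pls(
                    X, y, n_components=n_components
                ),
                return_predictions=True,
            )
        return PeptideAffinityResults(self, pls, cv, oof, seed=seed)

    def encode_names(self, names) -> np.ndarray:
        """Encode new epitope names with the already-fitted reducer."""
        rows = []
        for name in names:
            toks = tokenize(parse_epitope_name(name))
            rows.append(
                chem_encoder.encode_peptide(
                    toks, self.token_map, L_max=self.L_max, d=self.d
                )
            )
        return np.vstack(rows)


class PeptideAffinityResults:
    """Fit results: coefficients, diagnostics, CV metrics, sweep and benchmark."""

    def __init__(self, model: PeptideAffinityModel, pls, cv, oof, seed: int = 0):
        self.model = model
        self.pls = pls
        self.cross_validation = cv
        self._oof = oof
        self.seed = seed
        self.fittedvalues = pls.predict(model.exog)
        self.resid = model.endog - self.fittedvalues

    # -- scalar diagnostics -------------------------------------------- #
    @property
    def params(self) -> np.ndarray:
        """PLS regression coefficients in the assembled feature space."""
        return self.pls.coef

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def rsquared(self) -> float:
        """Training R² (in-sample)."""
        return regression.r_squared(self.model.endog, self.fittedvalues)

    @property
    def rmse(self) -> float:
        """Training RMSE (in-sample), log10(nM) units."""
        return regression.rmse(self.model.endog, self.fittedvalues)

    @property
    def cv_rsquared(self) -> float:
        return self.cross_validation.mean_r2

    @property
    def cv_rmse(self) -> float:
        return self.cross_validation.mean_rmse

    # -- prediction ----------------------------------------------------- #
    def predict(self, names=None, exog=None) -> np.ndarray:
        """Predict log10(IC50 nM) for epitope names or pre-encoded features."""
        if (names is None) == (exog is None):
            raise ValueError("give exactly one of names or exog")
        if exog is None:
            exog = self.model.encode_names(names)
        return self.pls.predict(exog)

    def predict_ic50(self, names) -> np.ndarray:
        """Predicted IC50 in nM."""
        return np.power(10.0, self.predict(names=names))

    def prediction_frame(self) -> pd.DataFrame:
        """Per-record actual/predicted/fold table (scatter-ready, out-of-fold)."""
        frame = pd.DataFrame(
            {
                "name": self.model.names,
                "actual_log10_ic50": self.model.endog,
                "fitted_log10_ic50": self.fittedvalues,
            }
        )
        if self._oof is not None:
            frame["cv_predicted_log10_ic50"] = self._oof[:, 0]
            frame["cv_fold"] = self._oof[:, 1].astype(int)
        return frame

    # -- protocol extensions -------------------------------------------- #
    def component_sweep(self, A_range=range(2, 11), k: int = 5, seed=None):
        seed = self.seed if seed is None else seed
        return regression.component_sweep(
            self.model.exog, self.model.endog, A_range=A_range, k=k, seed=seed
        )

    def benchmark(self, k: int = 5, seed=None):
        seed = self.seed if seed is None else seed
        return regression.benchmark(self.model.exog, self.model.endog, k=k, seed=seed)

    # -- presentation ---------------------------------------------------- #
    def summary(self) -> str:
        """Plain-text summary table in the statsmodels style."""
        m = self.model
        lines = [
            "            Peptide Affinity PLS Regression Results",
            "=" * 62,
            f"Dep. Variable:      log10(IC50 nM)   No. Observations: {self.nobs:>7d}",
            f"Model:              PLS ({self.pls.n_components} comp.)    "
            f"Feature dimension: {m.exog.shape[1]:>6d}",
            f"Registry tokens:    {len(m.registry):>5d}            "
            f"Reduced dim (d):   {m.d:>6d}",
            "-" * 62,
            f"Training R-squared:        {self.rsquared:8.3f}",
            f"Training RMSE:             {self.rmse:8.3f}",
        ]
        if self.cross_validation is not None:
            cv = self.cross_validation
            lines += [
                f"CV ({cv.k}-fold) R-squared:     {cv.mean_r2:8.3f}",
                f"CV ({cv.k}-fold) RMSE:          {cv.mean_rmse:8.3f}",
                "-" * 62,
                "Fold     held-out R2    held-out RMSE",
            ]
            for i, (r2, e) in enumerate(cv.per_fold):
                lines.append(f"{i:>4d}     {r2:>11.3f}    {e:>13.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Actual vs predicted log10(IC50) scatter, colour-split train/held-out."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        y = self.model.endog
        ax.scatter(y, self.fittedvalues, s=18, c="firebrick", label="training (fitted)")
        if self._oof is not None:
            ax.scatter(
                y, self._oof[:, 0], s=18, c="steelblue", label="held-out (CV)"
            )
        lo, hi = float(min(y.min(), self.fittedvalues.min())), float(
            max(y.max(), self.fittedvalues.max())
        )
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(r"actual $\log_{10}$(IC50 / nM)")
        ax.set_ylabel(r"predicted $\log_{10}$(IC50 / nM)")
        ax.legend(frameon=False)
        return ax

    def save(self, path, config: dict | None = None) -> None:
        regression.save_model(
            path,
            self.pls,
            config=config
            or {"d": self.model.d, "L_max": self.model.L_max, "seed": self.seed},
            data_hash=regression.array_hash(self.model.exog, self.model.endog),
        )
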