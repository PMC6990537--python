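"""Design construction shared by cause-specific and subdistribution fits.

Parameter layout for a single-baseline model:

    theta = [ gamma_0 (intercept), gamma_1..gamma_df (spline),
              beta_1..beta_p (covariates),
              one block per time-varying coefficient (tvc) ]

A tvc block interacts one covariate with a time basis: either the single
``ln t`` column (``tvc_df=1``, the default for likelihood-ratio testing of
proportionality) or the full baseline spline basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .splines import KnotSet, ncs_basis, ncs_derivative


@dataclass(frozen=True)
class TVCTerm:
    """Covariate x time-basis interaction."""

    covariate: str
    time_fn: str = "log"  # "log" (ln t only) or "spline" (full baseline basis)

    def n_cols(self, knots: KnotSet) -> int:
        return 1 if self.time_fn == "log" else knots.df

    def basis(self, logt: np.ndarray, knots: KnotSet) -> np.ndarray:
        if self.time_fn == "log":
            return logt[:, None]
        return ncs_basis(logt, knots)

    def dbasis(self, logt: np.ndarray, knots: KnotSet) -> np.ndarray:
        if self.time_fn == "log":
            return np.ones((logt.size, 1))
        return ncs_derivative(logt, knots)


@dataclass(frozen=True)
class ModelDesign:
    """Maps (log time, covariates) to the engine design matrices."""

    knots: KnotSet
    covariate_names: tuple[str, ...]
    tvc: tuple[TVCTerm, ...] = ()

    @property
    def n_params(self) -> int:
        return 1 + self.knots.df + len(self.covariate_names) + sum(
            t.n_cols(self.knots) for t in self.tvc
        )

    def param_names(self) -> list[str]:
        names = ["gamma0"] + [f"gamma{j}" for j in range(1, self.knots.df + 1)]
        names += list(self.covariate_names)
        for term in self.tvc:
            names += [
                f"{term.covariate}:t{j}" for j in range(1, term.n_cols(self.knots) + 1)
            ]
        return names

    def _cov_index(self, name: str) -> int:
        return self.covariate_names.index(name)

    def build(self, logt: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (Z, Zd): the design for ln H and its d/dlnt."""
        n = logt.size
        B = ncs_basis(logt, self.knots)
        dB = ncs_derivative(logt, self.knots)
        cols = [np.ones((n, 1)), B, X]
        dcols = [np.zeros((n, 1)), dB, np.zeros_like(X)]
        for term in self.tvc:
            x = X[:, self._cov_index(term.covariate)][:, None]
            cols.append(x * term.basis(logt, self.knots))
            dcols.append(x * term.dbasis(logt, self.knots))
        return np.hstack(cols), np.hstack(dcols)

    def check_rank(self, X: np.ndarray) -> None:
        q = X.shape[1]
        if q == 0:
            return
        full = np.hstack([np.ones((X.shape[0], 1)), X])
        if np.linalg.matrix_rank(full) < q + 1:
            raise np.linalg.LinAlgError(
                "design matrix rank-deficient (constant or collinear covariates)"
            )


def split_theta(design: ModelDesign, theta: np.ndarray):
    """Split a flat parameter vector into (gamma, beta, tvc dict)."""
    df = design.knots.df
    p = len(design.covariate_names)
    gamma = theta[: df + 1]
    beta = theta[df + 1 : df + 1 + p]
    tvc = {}
    ofs = df + 1 + p
    for term in design.tvc:
        m = term.n_cols(design.knots)
        tvc[term.covariate] = theta[ofs : ofs + m]
        ofs += m
    return gamma, beta, tvc
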