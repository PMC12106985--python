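"""Bayesian hierarchical spatial logistic model and its Gibbs sampler.

The model for the probability ``p_i`` that girl ``i`` is cut is

    logit(p_i) = b0 + z_i' b + f_1(x_i1) + ... + f_p(x_ip)
                 + f_str(s_i) + f_unstr(s_i) + b_w * weight_i

with reference-coded fixed effects ``b`` (vague N(0, 1000) priors),
random-walk-order-2 smooths ``f_k`` over binned covariate grids (one
sum-to-zero constraint each), a Besag ICAR structured state effect
``f_str`` (sum-to-zero per graph component) and an iid Gaussian
unstructured state effect ``f_unstr``.  All precision hyperparameters get
Gamma(a, b) priors (default Gamma(1, 5e-5)).

Inference is an exact MCMC scheme: Pólya-Gamma data augmentation makes the
Bernoulli-logit likelihood conditionally Gaussian, so each sweep draws
(i) the latent ``omega_i ~ PG(1, eta_i)``, (ii) all linear blocks jointly
from their Gaussian full conditional (sum-to-zero constraints enforced by
conditioning-by-kriging after the draw), and (iii) the precisions from
conjugate Gamma full conditionals.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import expit

from .design import DesignMatrices, ModelSpec, build_design
from .geo import AdjacencyGraph, ICARStructure, icar_precision
from .pg import polya_gamma, seed_pg

logger = logging.getLogger(__name__)

__all__ = ["Priors", "BayesSpatialLogit", "BayesSpatialLogitResults", "load_draws"]

_P_CLIP = 1e-12


@dataclass(frozen=True)
class Priors:
    """Hyperprior settings.

    ``fixed_prec``: prior precision of fixed effects (1e-3 = N(0, 1000)).
    ``tau_a``/``tau_b``: Gamma prior on every precision hyperparameter (the
    spatial-epidemiology default Gamma(1, 5e-5)).  ``jitter`` is a small
    diagonal added to intrinsically singular penalty blocks; the draw is
    subsequently corrected exactly onto the constraint subspace.
    """

    fixed_prec: float = 1e-3
    tau_a: float = 1.0
    tau_b: float = 5e-5
    jitter: float = 1e-6

    def to_dict(self) -> dict:
        return {
            "fixed_prec": self.fixed_prec,
            "tau_a": self.tau_a,
            "tau_b": self.tau_b,
            "jitter": self.jitter,
        }


def _rw2_penalty(k: int) -> np.ndarray:
    """Second-difference penalty D2' D2 over a k-point grid (rank k-2)."""
    if k < 3:
        return np.eye(k) * 0.0
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    return D.T @ D


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """D = -2 sum log Bern(y | p), with probabilities clipped away from 0/1."""
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


class BayesSpatialLogit:
    """Hierarchical spatial logistic model for girl-level cut/uncut data.

    Parameters
    ----------
    design
        Encoded design blocks (see :func:`fgmspatial.design.build_design`).
    spec
        Model specification (complexity m1/m2/m3 and covariate set).
    structure
        ICAR structure over states; required for m2/m3.
    priors
        Hyperprior settings.
    """

    def __init__(
        self,
        design: DesignMatrices,
        spec: ModelSpec | None = None,
        structure: ICARStructure | None = None,
        priors: Priors | None = None,
    ):
        spec = spec or design.info.spec
        if spec.has_structured and structure is None:
            raise ValueError(f"{spec.complexity} requires an ICAR structure")
        if structure is not None and spec.has_structured:
            if tuple(structure.graph.node_ids) != tuple(design.info.state_labels):
                raise ValueError("design state labels do not match the adjacency graph")
        self.design = design
        self.spec = spec
        self.structure = structure if spec.has_structured else None
        self.priors = priors or Priors()
        self._assemble()

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        spec: ModelSpec | None = None,
        graph: AdjacencyGraph | None = None,
        priors: Priors | None = None,
    ) -> "BayesSpatialLogit":
        """Build the model from validated girl records.

        For spatial specifications an adjacency graph over the record
        states is required; community-covariate sets expect the cluster
        profile columns to be merged in already (see
        :func:`fgmspatial.community.attach_community`).
        """
        spec = spec or ModelSpec()
        structure = None
        labels = None
        if spec.has_structured:
            if graph is None:
                raise ValueError("spatial model requires an adjacency graph")
            structure = icar_precision(graph)
            labels = graph.node_ids
        design = build_design(records, spec, state_labels=labels)
        return cls(design, spec, structure, priors)

    # -- internal assembly -------------------------------------------------

    def _assemble(self) -> None:
        d = self.design
        n = d.n
        blocks: list[sp.csr_matrix] = [sp.csr_matrix(d.X_fixed)]
        names: list[str] = list(d.fixed_names)
        slices: dict[str, slice] = {"fixed": slice(0, d.X_fixed.shape[1])}
        pos = d.X_fixed.shape[1]
        rows = np.arange(n)
        for sname in d.info.smooth_names:
            k = len(d.smooth_grids[sname])
            idx = d.smooth_idx[sname]
            B = sp.csr_matrix((np.ones(n), (rows, idx)), shape=(n, k))
            blocks.append(B)
            names += [f"{sname}@{g:g}" for g in d.smooth_grids[sname]]
            slices[sname] = slice(pos, pos + k)
            pos += k
        if self.spec.has_structured:
            ns = self.structure.n
            S = sp.csr_matrix((np.ones(n), (rows, d.state_index)), shape=(n, ns))
            blocks.append(S)
            names += [f"u_str[{s}]" for s in self.structure.graph.node_ids]
            slices["u_str"] = slice(pos, pos + ns)
            pos += ns
            if self.spec.has_unstructured:
                blocks.append(S.copy())
                names += [f"v_unstr[{s}]" for s in self.structure.graph.node_ids]
                slices["v_unstr"] = slice(pos, pos + ns)
                pos += ns
        self._X = sp.hstack(blocks, format="csr")
        self._Xt = self._X.T.tocsr()
        self.coef_names = names
        self.block_slices = slices
        self.n_coef = pos
        self._penalties: dict[str, np.ndarray] = {
            sname: _rw2_penalty(len(d.smooth_grids[sname]))
            for sname in d.info.smooth_names
        }
        cons_rows = []
        for sname in d.info.smooth_names:
            row = np.zeros(pos)
            row[slices[sname]] = 1.0
            cons_rows.append(row)
        if self.spec.has_structured:
            for comp in self.structure.constraints:
                row = np.zeros(pos)
                row[slices["u_str"]] = comp
                cons_rows.append(row)
        self._A = np.array(cons_rows) if cons_rows else np.zeros((0, pos))

    def _prior_precision(self, taus: dict[str, float]) -> np.ndarray:
        pr = self.priors
        P = np.zeros((self.n_coef, self.n_coef))
        sl = self.block_slices["fixed"]
        P[sl, sl] += np.eye(sl.stop - sl.start) * pr.fixed_prec
        for sname, K in self._penalties.items():
            sl = self.block_slices[sname]
            P[sl, sl] += taus[sname] * K + pr.jitter * np.eye(K.shape[0])
        if self.spec.has_structured:
            sl = self.block_slices["u_str"]
            P[sl, sl] += (
                taus["u_str"] * self.structure.Q.toarray()
                + pr.jitter * np.eye(self.structure.n)
            )
            if self.spec.has_unstructured:
                sl = self.block_slices["v_unstr"]
                P[sl, sl] += taus["v_unstr"] * np.eye(self.structure.n)
        return P

    # -- sampling ----------------------------------------------------------

    def fit(
        self,
        iterations: int = 4000,
        burn_in: int = 1000,
        thin: int = 1,
        seed: int = 0,
    ) -> "BayesSpatialLogitResults":
        """Run the Pólya-Gamma Gibbs sampler and return posterior draws."""
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
        seed_pg(int(np.random.SeedSequence((int(seed), 103)).generate_state(1)[0]))

        d = self.design
        y = d.y
        kappa = y - 0.5
        rhs_data = self._Xt @ kappa
        theta = np.zeros(self.n_coef)
        taus = {s: 10.0 for s in d.info.smooth_names}
        if self.spec.has_structured:
            taus["u_str"] = 10.0
        if self.spec.has_unstructured:
            taus["v_unstr"] = 10.0
        a0, b0 = self.priors.tau_a, self.priors.tau_b

        n_keep = (iterations - burn_in + thin - 1) // thin
        theta_draws = np.empty((n_keep, self.n_coef))
        tau_draws = {k: np.empty(n_keep) for k in taus}
        dev_draws = np.empty(n_keep)
        keep = 0
        A = self._A
        for it in range(iterations):
            eta = self._X @ theta
            omega = polya_gamma(eta)
            Xw = self._X.multiply(omega[:, None])
            Lam = (self._Xt @ Xw).toarray() + self._prior_precision(taus)
            if not np.isfinite(Lam).all():
                raise FloatingPointError("non-finite full-conditional precision")
            try:
                L = cholesky(Lam, lower=True)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise FloatingPointError(
                    "full-conditional precision not positive definite"
                ) from e
            m = cho_solve((L, True), rhs_data)
            z = rng.standard_normal(self.n_coef)
            theta = m + solve_triangular(L.T, z, lower=False)
            if A.shape[0]:
                V = cho_solve((L, True), A.T)
                W = A @ V
                theta = theta - V @ np.linalg.solve(W, A @ theta)
            for sname, K in self._penalties.items():
                sl = self.block_slices[sname]
                th = theta[sl]
                quad = float(th @ K @ th)
                rank = max(K.shape[0] - 2, 0)
                taus[sname] = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * quad))
            if self.spec.has_structured:
                sl = self.block_slices["u_str"]
                u = theta[sl]
                quad = float(u @ (self.structure.Q @ u))
                taus["u_str"] = rng.gamma(
                    a0 + 0.5 * self.structure.rank, 1.0 / (b0 + 0.5 * quad)
                )
            if self.spec.has_unstructured:
                sl = self.block_slices["v_unstr"]
                v = theta[sl]
                taus["v_unstr"] = rng.gamma(
                    a0 + 0.5 * len(v), 1.0 / (b0 + 0.5 * float(v @ v))
                )
            if it >= burn_in and (it - burn_in) % thin == 0:
                eta_new = self._X @ theta
                dev = bernoulli_deviance(y, expit(eta_new))
                if not np.isfinite(dev):
                    raise FloatingPointError("non-finite deviance draw")
                theta_draws[keep] = theta
                for k in taus:
                    tau_draws[k][keep] = taus[k]
                dev_draws[keep] = dev
                keep += 1
        return BayesSpatialLogitResults(
            model=self,
            theta_draws=theta_draws[:keep],
            tau_draws={k: v[:keep] for k, v in tau_draws.items()},
            deviance_draws=dev_draws[:keep],
            mcmc={"iterations": iterations, "burn_in": burn_in, "thin": thin, "seed": int(seed)},
        )


class BayesSpatialLogitResults:
    """Posterior draws of all model blocks plus per-draw deviance."""

    def __init__(
        self,
        model: BayesSpatialLogit,
        theta_draws: np.ndarray,
        tau_draws: dict[str, np.ndarray],
        deviance_draws: np.ndarray,
        mcmc: dict,
    ):
        self.model = model
        self.theta_draws = theta_draws
        self.tau_draws = tau_draws
        self.deviance_draws = deviance_draws
        self.mcmc = mcmc

    # -- basic accessors ---------------------------------------------------

    @property
    def n_draws(self) -> int:
        return self.theta_draws.shape[0]

    @property
    def coef_names(self) -> list[str]:
        return self.model.coef_names

    def block(self, name: str) -> np.ndarray:
        """Draws of one block (n_draws, block size)."""
        return self.theta_draws[:, self.model.block_slices[name]]

    def posterior_mean(self) -> np.ndarray:
        return self.theta_draws.mean(axis=0)

    # -- prediction --------------------------------------------------------

    def _matrix_for(self, design: DesignMatrices | None) -> sp.csr_matrix:
        if design is None:
            return self.model._X
        m = BayesSpatialLogit(
            design,
            self.model.spec,
            self.model.structure,
            self.model.priors,
        )
        if m.coef_names != self.model.coef_names:
            raise ValueError("new design is not encoded like the fitted design")
        return m._X

    def linear_predictor(
        self, draw_index: int, design: DesignMatrices | None = None
    ) -> np.ndarray:
        """Per-record eta for one stored draw."""
        if not 0 <= draw_index < self.n_draws:
            raise IndexError(f"draw {draw_index} out of range [0, {self.n_draws})")
        X = self._matrix_for(design)
        return X @ self.theta_draws[draw_index]

    def predict_proba(
        self,
        records: pd.DataFrame | None = None,
        max_draws: int = 200,
    ) -> np.ndarray:
        """Posterior-mean probability per record.

        New records are encoded with the fitted design's frozen encoding;
        draws are thinned to at most ``max_draws`` for scoring.
        """
        if records is None:
            design = None
        else:
            design = build_design(records, like=self.model.design.info, spec=None)
        X = self._matrix_for(design)
        step = max(1, self.n_draws // max_draws)
        idx = np.arange(0, self.n_draws, step)
        p = np.zeros(X.shape[0])
        for i in idx:
            p += expit(X @ self.theta_draws[i])
        return p / len(idx)

    def prob_draws(
        self, design: DesignMatrices | None = None, max_draws: int | None = None
    ) -> np.ndarray:
        """(n_used_draws, n_records) matrix of per-draw probabilities."""
        X = self._matrix_for(design)
        if max_draws is None or max_draws >= self.n_draws:
            idx = np.arange(self.n_draws)
        else:
            idx = np.linspace(0, self.n_draws - 1, max_draws).astype(int)
        return expit((X @ self.theta_draws[idx].T).T)

    # -- deviance / DIC ----------------------------------------------------

    def deviance_at_mean(self) -> float:
        """Deviance evaluated at the posterior means of all blocks."""
        eta = self.model._X @ self.posterior_mean()
        return bernoulli_deviance(self.model.design.y, expit(eta))

    def dic(self) -> dict[str, float]:
        """Deviance information criterion with the plug-in pD.

        Dbar = mean posterior deviance, pD = Dbar - D(theta_bar),
        DIC = Dbar + pD.
        """
        if not np.isfinite(self.deviance_draws).all():
            raise FloatingPointError("non-finite deviance draws")
        dbar = float(self.deviance_draws.mean())
        pd_ = dbar - self.deviance_at_mean()
        return {"Dbar": dbar, "pD": pd_, "DIC": dbar + pd_}

    # -- summaries ---------------------------------------------------------

    def odds_ratios(self) -> pd.DataFrame:
        """Posterior odds ratios of the fixed effects with 95% intervals.

        POR = exp(posterior mean coefficient); interval endpoints are the
        exponentials of the 2.5/97.5% coefficient quantiles.  A level is
        significant when both endpoints sit on the same side of 1.
        Reference levels are included with POR 1.
        """
        fixed = self.block("fixed")
        names = self.coef_names[self.model.block_slices["fixed"]]
        from .schema import CATEGORIES

        rows = []
        seen_cov: set[str] = set()
        for j, name in enumerate(names):
            if "[" in name:
                cov, lev = name[:-1].split("[")
            else:
                cov, lev = name, ""
            if cov in CATEGORIES and cov not in seen_cov:
                seen_cov.add(cov)
                rows.append(
                    {
                        "covariate": cov,
                        "level": CATEGORIES[cov][0] + " (ref)",
                        "POR": 1.0,
                        "q2.5": np.nan,
                        "q97.5": np.nan,
                        "significant": False,
                    }
                )
            draws = fixed[:, j]
            lo, hi = np.exp(np.quantile(draws, [0.025, 0.975]))
            rows.append(
                {
                    "covariate": cov,
                    "level": lev,
                    "POR": float(np.exp(draws.mean())),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "significant": bool((lo > 1 and hi > 1) or (lo < 1 and hi < 1)),
                }
            )
        return pd.DataFrame(rows)

    def state_prevalence(self, max_draws: int = 300) -> pd.DataFrame:
        """Posterior state-level weighted prevalence (mean, SD, 95% interval).

        For each draw the per-state weighted mean of ``p_i`` over that
        state's records is computed; summaries are over draws, on the
        percent scale.  The row ``state_id='(national)'`` aggregates all
        records.
        """
        d = self.model.design
        labels = list(d.info.state_labels)
        P = self.prob_draws(max_draws=max_draws)  # (draws, n)
        w = d.weight
        rows = []
        per_state = {}
        for si, lab in enumerate(labels):
            m = d.state_index == si
            if not m.any():
                logger.warning("state %s has no records; omitted", lab)
                continue
            wp = (P[:, m] * w[m]).sum(axis=1) / w[m].sum()
            per_state[lab] = wp
        nat = (P * w).sum(axis=1) / w.sum()
        for lab, wp in [*per_state.items(), ("(national)", nat)]:
            q = np.quantile(wp, [0.025, 0.975])
            rows.append(
                {
                    "state_id": lab,
                    "mean_pct": 100 * float(wp.mean()),
                    "sd_pct": 100 * float(wp.std(ddof=0)),
                    "q2.5_pct": 100 * float(q[0]),
                    "q97.5_pct": 100 * float(q[1]),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary: fit info, DIC, fixed-effect POR table."""
        spec = self.model.spec
        dic = self.dic()
        lines = [
            "Bayesian hierarchical spatial logistic model",
            f"  complexity: {spec.complexity}   covariates: {spec.covariate_set}",
            f"  records: {self.model.design.n}   coefficients: {self.model.n_coef}",
            f"  draws: {self.n_draws} (iterations {self.mcmc['iterations']}, "
            f"burn-in {self.mcmc['burn_in']}, thin {self.mcmc['thin']}, "
            f"seed {self.mcmc['seed']})",
            f"  Dbar {dic['Dbar']:.1f}   pD {dic['pD']:.1f}   DIC {dic['DIC']:.1f}",
            "",
            f"{'covariate':<18}{'level':<16}{'POR':>9}{'2.5%':>9}{'97.5%':>9}  sig",
        ]
        for _, r in self.odds_ratios().iterrows():
            lo = "-" if np.isnan(r["q2.5"]) else f"{r['q2.5']:.3f}"
            hi = "-" if np.isnan(r["q97.5"]) else f"{r['q97.5']:.3f}"
            lines.append(
                f"{r['covariate']:<18}{r['level']:<16}{r['POR']:>9.3f}{lo:>9}{hi:>9}"
                f"  {'*' if r['significant'] else ''}"
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        """Persist the draw archive as draws.csv + meta.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.theta_draws, columns=self.coef_names)
        for k, v in self.tau_draws.items():
            df[f"tau[{k}]"] = v
        df["deviance"] = self.deviance_draws
        df.to_csv(out / "draws.csv", index=False)
        meta = {
            "spec": self.model.spec.to_dict(),
            "priors": self.model.priors.to_dict(),
            "mcmc": self.mcmc,
            "coef_names": self.coef_names,
            "tau_blocks": list(self.tau_draws),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_draws(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Load a persisted draw archive (draws frame, meta dict)."""
    out = Path(out_dir)
    df = pd.read_csv(out / "draws.csv")
    meta = json.loads((out / "meta.json").read_text())
    return df, meta
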