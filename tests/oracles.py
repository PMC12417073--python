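"""Independent oracles used to check the package's LP and overlap paths.

These deliberately avoid cobra/optlang and the package's analytic overlap
code: flux intervals are obtained by brute-force vertex enumeration of the
flux polytope {v : S·v = 0, lb ≤ v ≤ ub}, and the overlap index by dense
trapezoidal quadrature of min(φ1, φ2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np

from retap.model_io import MetabolicModel


def stoichiometric_matrix(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S, lb, ub) with metabolite rows / reaction columns in model order."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    lb = np.empty(len(model.reactions))
    ub = np.empty(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for mid, coef in rxn.stoichiometry.items():
            S[met_index[mid], j] = coef
    return S, lb, ub


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """All vertices of {v : S v = 0, lb ≤ v ≤ ub} (bounded polytope assumed).

    A vertex fixes (n − rank S) coordinates at a bound with the remaining
    square system nonsingular; every such candidate is solved and kept if
    feasible.  Exponential, so only for tiny models.
    """
    n = S.shape[1]
    r = int(np.linalg.matrix_rank(S))
    k = n - r
    verts: list[np.ndarray] = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for choice in itertools.product((0, 1), repeat=k):
            vals = np.array([lb[j] if c == 0 else ub[j] for j, c in zip(fixed, choice)])
            if not np.all(np.isfinite(vals)):
                continue
            b = -S[:, fixed] @ vals
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.linalg.norm(A @ sol - b) > tol:
                continue  # inconsistent face
            v = np.empty(n)
            v[free] = sol
            v[list(fixed)] = vals
            if np.all(v >= lb - tol) and np.all(v <= ub + tol) and np.max(np.abs(S @ v)) <= tol:
                verts.append(v)
    if not verts:
        return np.empty((0, n))
    return np.array(verts)


def fva_by_vertex_enumeration(
    model: MetabolicModel, extra_bounds: dict[str, tuple[float, float]] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] feasible flux via vertex enumeration."""
    if extra_bounds:
        new = []
        for r in model.reactions:
            if r.id in extra_bounds:
                lo, hi = extra_bounds[r.id]
                r = replace(r, lower_bound=max(r.lower_bound, lo), upper_bound=min(r.upper_bound, hi))
            new.append(r)
        model = replace(model, reactions=tuple(new))
    S, lb, ub = stoichiometric_matrix(model)
    verts = enumerate_vertices(S, lb, ub)
    if verts.size == 0:
        raise ValueError("polytope is empty (infeasible)")
    return {
        rxn.id: (float(verts[:, j].min()), float(verts[:, j].max()))
        for j, rxn in enumerate(model.reactions)
    }


def overlap_by_quadrature(mu1: float, s1: float, mu2: float, s2: float, n_grid: int = 200_001) -> float:
    """∫ min(φ1, φ2) dx on a dense grid over the joint ±8σ envelope."""
    lo = min(mu1 - 8 * s1, mu2 - 8 * s2)
    hi = max(mu1 + 8 * s1, mu2 + 8 * s2)
    x = np.linspace(lo, hi, n_grid)
    pdf1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    pdf2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return float(np.trapezoid(np.minimum(pdf1, pdf2), x))


def equal_sigma_overlap(mu1: float, mu2: float, sigma: float) -> float:
    """Closed form for equal spreads: 2Φ(−|Δµ| / (2σ))."""
    return float(2.0 * 0.5 * math.erfc(abs(mu1 - mu2) / (2.0 * sigma) / math.sqrt(2.0)))


def strip_decoy(model: MetabolicModel) -> MetabolicModel:
    """Drop the decoy pathway from a branched toy, leaving the ≤8-reaction
    planted core for the exponential vertex oracle."""
    decoy_rxns = {"EX_X", "R_X", "EX_Y"}
    decoy_mets = {"X_c", "Y_c"}
    return replace(
        model,
        reactions=tuple(r for r in model.reactions if r.id not in decoy_rxns),
        metabolites=tuple(m for m in model.metabolites if m.id not in decoy_mets),
    )
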