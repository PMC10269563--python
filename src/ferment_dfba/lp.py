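"""Persistent linear-programming layer for repeated FBA / pFBA solves.

dFBA solves a structurally identical LP thousands of times along a
trajectory, with only bounds, the objective and (for the dynamic biomass
equation) a single matrix column changing between solves.  GLPK keeps a
warm simplex basis across such edits, which makes each re-solve orders of
magnitude cheaper than rebuilding the problem.  This module wraps swiglpk
in just enough API for that use, plus the two-stage parsimonious FBA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import swiglpk as glp

INF = float("inf")

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {
    glp.GLP_OPT: OPTIMAL,
    glp.GLP_FEAS: "feasible",
    glp.GLP_INFEAS: INFEASIBLE,
    glp.GLP_NOFEAS: INFEASIBLE,
    glp.GLP_UNBND: UNBOUNDED,
    glp.GLP_UNDEF: "undefined",
}


def _bounds_type(lo: float, hi: float):
    if lo == -INF and hi == INF:
        return glp.GLP_FR
    if lo == -INF:
        return glp.GLP_UP
    if hi == INF:
        return glp.GLP_LO
    if lo == hi:
        return glp.GLP_FX
    return glp.GLP_DB


class PersistentLP:
    """A GLPK problem kept alive across bound/objective edits.

    Rows and columns are 0-indexed at this interface (GLPK is 1-indexed
    internally).  All rows are linear constraints with [row_lb, row_ub]
    bounds; columns carry [col_lb, col_ub] bounds and objective
    coefficients.
    """

    def __init__(self, A, row_lb, row_ub, col_lb, col_ub, obj=None,
                 maximize=True, name="lp"):
        A = np.asarray(A, dtype=float)
        self.m, self.n = A.shape
        self._prob = glp.glp_create_prob()
        glp.glp_set_prob_name(self._prob, name)
        glp.glp_add_rows(self._prob, self.m)
        glp.glp_add_cols(self._prob, self.n)
        self._row_lb = np.array(row_lb, dtype=float)
        self._row_ub = np.array(row_ub, dtype=float)
        self._col_lb = np.array(col_lb, dtype=float)
        self._col_ub = np.array(col_ub, dtype=float)
        for i in range(self.m):
            self._push_row_bounds(i)
        for j in range(self.n):
            self._push_col_bounds(j)
        nz = np.nonzero(A)
        k = len(nz[0])
        ia = glp.intArray(k + 1)
        ja = glp.intArray(k + 1)
        ar = glp.doubleArray(k + 1)
        for idx, (i, j) in enumerate(zip(nz[0], nz[1]), start=1):
            ia[idx] = int(i) + 1
            ja[idx] = int(j) + 1
            ar[idx] = float(A[i, j])
        glp.glp_load_matrix(self._prob, k, ia, ja, ar)
        glp.glp_set_obj_dir(self._prob,
                            glp.GLP_MAX if maximize else glp.GLP_MIN)
        self._obj = np.zeros(self.n)
        if obj is not None:
            self.set_objective(obj)
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self._parm.presolve = glp.GLP_OFF
        self._have_basis = False

    # -- editing -----------------------------------------------------------
    def _push_row_bounds(self, i):
        lo, hi = self._row_lb[i], self._row_ub[i]
        glp.glp_set_row_bnds(self._prob, i + 1, _bounds_type(lo, hi),
                             0.0 if lo == -INF else lo,
                             0.0 if hi == INF else hi)

    def _push_col_bounds(self, j):
        lo, hi = self._col_lb[j], self._col_ub[j]
        glp.glp_set_col_bnds(self._prob, j + 1, _bounds_type(lo, hi),
                             0.0 if lo == -INF else lo,
                             0.0 if hi == INF else hi)

    def set_col_bounds(self, j, lo, hi):
        if self._col_lb[j] != lo or self._col_ub[j] != hi:
            self._col_lb[j] = lo
            self._col_ub[j] = hi
            self._push_col_bounds(j)

    def set_col_bounds_array(self, lb, ub, n=None):
        """Bulk bound update for the first n columns; touches only
        columns whose bounds actually changed."""
        n = self.n if n is None else n
        changed = np.nonzero((self._col_lb[:n] != lb) |
                             (self._col_ub[:n] != ub))[0]
        self._col_lb[:n] = lb
        self._col_ub[:n] = ub
        for j in changed:
            self._push_col_bounds(int(j))

    def set_row_bounds(self, i, lo, hi):
        if self._row_lb[i] != lo or self._row_ub[i] != hi:
            self._row_lb[i] = lo
            self._row_ub[i] = hi
            self._push_row_bounds(i)

    def set_objective(self, c):
        c = np.asarray(c, dtype=float)
        changed = np.nonzero(c != self._obj)[0]
        for j in changed:
            glp.glp_set_obj_coef(self._prob, int(j) + 1, float(c[j]))
        self._obj = c.copy()

    def set_col_entries(self, j, rows, vals):
        """Replace the nonzero pattern of column j (0-indexed rows)."""
        k = len(rows)
        ind = glp.intArray(k + 1)
        val = glp.doubleArray(k + 1)
        for idx, (i, v) in enumerate(zip(rows, vals), start=1):
            ind[idx] = int(i) + 1
            val[idx] = float(v)
        glp.glp_set_mat_col(self._prob, j + 1, k, ind, val)

    def set_row_entries(self, i, cols, vals):
        k = len(cols)
        ind = glp.intArray(k + 1)
        val = glp.doubleArray(k + 1)
        for idx, (j, v) in enumerate(zip(cols, vals), start=1):
            ind[idx] = int(j) + 1
            val[idx] = float(v)
        glp.glp_set_mat_row(self._prob, i + 1, k, ind, val)

    # -- solving -----------------------------------------------------------
    def solve(self):
        if not self._have_basis:
            glp.glp_adv_basis(self._prob, 0)
        ret = glp.glp_simplex(self._prob, self._parm)
        if ret != 0:
            # numerical trouble with the warm basis: rebuild and retry
            glp.glp_adv_basis(self._prob, 0)
            ret = glp.glp_simplex(self._prob, self._parm)
        self._have_basis = ret == 0
        status = glp.glp_get_status(self._prob)
        prim = glp.glp_get_prim_stat(self._prob)
        dual = glp.glp_get_dual_stat(self._prob)
        if status == glp.GLP_OPT:
            return OPTIMAL
        if prim == glp.GLP_NOFEAS:
            return INFEASIBLE
        if status == glp.GLP_UNBND or (prim == glp.GLP_FEAS and
                                       dual == glp.GLP_NOFEAS):
            return UNBOUNDED
        return _STATUS.get(status, "undefined")

    def objective_value(self):
        return glp.glp_get_obj_val(self._prob)

    def primal(self, n=None):
        n = self.n if n is None else n
        out = np.empty(n)
        for j in range(n):
            out[j] = glp.glp_get_col_prim(self._prob, j + 1)
        return out

    def __del__(self):  # pragma: no cover
        try:
            glp.glp_delete_prob(self._prob)
        except Exception:
            pass


@dataclass
class FluxSolution:
    """Flux vector returned by one (p)FBA solve."""

    v: np.ndarray
    objective_value: float
    status: str
    message: str = ""


class FbaProblem:
    """Two-stage FBA/pFBA over a fixed stoichiometric structure.

    Stage 1 maximizes a linear objective c.v subject to S.v = 0 and flux
    bounds.  Stage 2 (parsimonious FBA) fixes c.v at its optimum (relative
    tolerance 1e-9) and minimizes the total absolute flux sum |v|, using
    auxiliary columns t_j >= |v_j|.  Both problems persist across calls so
    GLPK can warm-start.
    """

    REL_TOL = 1e-9

    def __init__(self, S, lb, ub):
        S = np.asarray(S, dtype=float)
        self.S = S
        self.m, self.n = S.shape
        lb = np.asarray(lb, dtype=float)
        ub = np.asarray(ub, dtype=float)
        self._fba = PersistentLP(S, np.zeros(self.m), np.zeros(self.m),
                                 lb, ub, maximize=True, name="fba")
        # pFBA: columns [v (n), t (n)], rows [S (m), c.v (1),
        #   v_j - t_j <= 0 (n), -v_j - t_j <= 0 (n)], minimize sum t
        m2 = self.m + 1 + 2 * self.n
        A2 = np.zeros((m2, 2 * self.n))
        A2[:self.m, :self.n] = S
        # objective row entries are set per solve
        for j in range(self.n):
            r1 = self.m + 1 + j
            r2 = self.m + 1 + self.n + j
            A2[r1, j] = 1.0
            A2[r1, self.n + j] = -1.0
            A2[r2, j] = -1.0
            A2[r2, self.n + j] = -1.0
        row_lb = np.concatenate([np.zeros(self.m), [-INF],
                                 np.full(2 * self.n, -INF)])
        row_ub = np.concatenate([np.zeros(self.m), [INF],
                                 np.zeros(2 * self.n)])
        col_lb = np.concatenate([lb, np.zeros(self.n)])
        col_ub = np.concatenate([ub, np.full(self.n, INF)])
        obj2 = np.concatenate([np.zeros(self.n), np.ones(self.n)])
        self._pfba = PersistentLP(A2, row_lb, row_ub, col_lb, col_ub,
                                  obj=obj2, maximize=False, name="pfba")
        self._pfba_obj_cols = np.array([], dtype=int)

    def set_bounds(self, lb, ub, pfba=True):
        self._fba.set_col_bounds_array(lb, ub)
        if pfba:
            self._pfba.set_col_bounds_array(lb, ub, n=self.n)

    def set_column(self, j, rows, vals):
        """Update stoichiometric column j in both problems."""
        self.S[:, j] = 0.0
        self.S[rows, j] = vals
        self._fba.set_col_entries(j, rows, vals)
        self._pfba.set_col_entries(j, list(rows) + [self.m + 1 + j,
                                                    self.m + 1 + self.n + j],
                                   list(vals) + [1.0, -1.0])

    def solve(self, c, pfba=True):
        c = np.asarray(c, dtype=float)
        self._fba.set_objective(c)
        status = self._fba.solve()
        if status != OPTIMAL:
            msg = self._diagnose(status)
            return FluxSolution(np.full(self.n, np.nan), np.nan, status, msg)
        z = self._fba.objective_value()
        if not pfba:
            return FluxSolution(self._fba.primal(), z, OPTIMAL)
        # stage 2: fix objective value, minimize total |v|
        cols = np.nonzero(c)[0]
        self._pfba.set_row_entries(self.m, cols, c[cols])
        slack = max(abs(z) * self.REL_TOL, 1e-12)
        self._pfba.set_row_bounds(self.m, z - slack, INF)
        status2 = self._pfba.solve()
        if status2 != OPTIMAL:
            # should not happen for a bounded stage 1; fall back to FBA vector
            return FluxSolution(self._fba.primal(), z, OPTIMAL,
                                f"pFBA stage returned {status2}")
        v = self._pfba.primal(self.n)
        return FluxSolution(v, z, OPTIMAL)

    def _diagnose(self, status):
        if status == INFEASIBLE:
            fixed = [j for j in range(self.n)
                     if self._fba._col_lb[j] == self._fba._col_ub[j]
                     and self._fba._col_lb[j] != 0.0]
            return ("infeasible under current bounds; equality-constrained "
                    f"columns: {fixed}")
        if status == UNBOUNDED:
            free = [j for j in range(self.n)
                    if self._fba._col_ub[j] == INF or
                    self._fba._col_lb[j] == -INF]
            return f"unbounded; columns with infinite bounds: {free}"
        return status
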