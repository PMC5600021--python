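"""One- and two-electron integrals over contracted Cartesian Gaussians.

McMurchie–Davidson scheme: Hermite expansion coefficients ``E`` for charge
distributions of Gaussian pairs, Hermite Coulomb integrals ``R`` built on the
Boys function.  Everything is in atomic units (bohr, hartree); geometry is
converted at the :class:`~cepair.qm.basis.BasisSet` boundary.

The engine is written for the small monomer/dimer systems this package
targets (tens of basis functions); clarity over raw speed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import hyp1f1

from .basis import BasisSet


def boys(mmax: int, T: float) -> np.ndarray:
    """Boys function values F_m(T) for m = 0..mmax."""
    m = np.arange(mmax + 1)
    return hyp1f1(m + 0.5, m + 1.5, -T) / (2 * m + 1)


def hermite_expansion(l1: int, l2: int, a: float, b: float, AB: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one Cartesian dimension."""
    p = a + b
    mu = a * b / p
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    PA = -b * AB / p  # P - A with AB = A - B
    PB = a * AB / p  # P - B
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                src = E[i - 1, 0]
                X = PA
            else:
                src = E[i, j - 1]
                X = PB
            for t in range(i + j + 1):
                val = X * src[t]
                if t > 0:
                    val += src[t - 1] / (2.0 * p)
                val += (t + 1) * src[t + 1]
                E[i, j, t] = val
    return E


def hermite_coulomb(tmax: int, umax: int, vmax: int, alpha: float, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R[t, u, v] (auxiliary order n = 0)."""
    N = tmax + umax + vmax
    T = alpha * float(PC @ PC)
    F = boys(N, T)
    R = np.zeros((N + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(N + 1):
        R[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for n in range(N - 1, -1, -1):
        for t in range(tmax + 1):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t + u + v == 0 or t + u + v + n > N:
                        continue
                    if t > 0:
                        val = PC[0] * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = PC[1] * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = PC[2] * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


class _Pair:
    """Primitive-pair Hermite data for one ordered basis-function pair."""

    __slots__ = ("p", "P", "coef", "Ex", "Ey", "Ez", "lab")

    def __init__(self, p, P, coef, Ex, Ey, Ez, lab):
        self.p = p
        self.P = P
        self.coef = coef
        self.Ex = Ex  # E[t] for the x powers of the two functions
        self.Ey = Ey
        self.Ez = Ez
        self.lab = lab  # (lx_sum, ly_sum, lz_sum)


class IntegralEngine:
    """Integrals over the functions of a :class:`BasisSet`.

    All matrices are returned in the individually normalised Cartesian
    basis-function order of the basis set.
    """

    def __init__(self, basis: BasisSet):
        self.basis = basis
        funcs = basis.function_shells
        self.n = len(funcs)
        self._alphas = [np.array(sh.exponents) for sh, _ in funcs]
        self._coefs = [np.array(sh.coefficients) for sh, _ in funcs]
        self._centers = [np.array(sh.center) for sh, _ in funcs]
        self._powers = [np.array(pw) for _, pw in funcs]
        self._pair_cache: dict[tuple[int, int], list[_Pair]] = {}
        self._norms = self._compute_norms()

    # -- plumbing ---------------------------------------------------------

    def _pairs(self, i: int, j: int) -> list[_Pair]:
        key = (i, j)
        if key in self._pair_cache:
            return self._pair_cache[key]
        A, B = self._centers[i], self._centers[j]
        la, lb = self._powers[i], self._powers[j]
        out = []
        for a, ca in zip(self._alphas[i], self._coefs[i]):
            for b, cb in zip(self._alphas[j], self._coefs[j]):
                p = a + b
                P = (a * A + b * B) / p
                Ex = hermite_expansion(la[0], lb[0], a, b, A[0] - B[0])[la[0], lb[0], : la[0] + lb[0] + 1]
                Ey = hermite_expansion(la[1], lb[1], a, b, A[1] - B[1])[la[1], lb[1], : la[1] + lb[1] + 1]
                Ez = hermite_expansion(la[2], lb[2], a, b, A[2] - B[2])[la[2], lb[2], : la[2] + lb[2] + 1]
                out.append(
                    _Pair(p, P, ca * cb, Ex, Ey, Ez, (la[0] + lb[0], la[1] + lb[1], la[2] + lb[2]))
                )
        self._pair_cache[key] = out
        return out

    def _compute_norms(self) -> np.ndarray:
        raw = np.empty(self.n)
        for i in range(self.n):
            raw[i] = self._overlap_element(i, i)
        return 1.0 / np.sqrt(raw)

    def _overlap_element(self, i: int, j: int) -> float:
        val = 0.0
        for pr in self._pairs(i, j):
            pref = (np.pi / pr.p) ** 1.5
            val += pr.coef * pref * pr.Ex[0] * pr.Ey[0] * pr.Ez[0]
        return val

    # -- one-electron integrals ------------------------------------------

    def overlap(self) -> np.ndarray:
        S = np.empty((self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1):
                S[i, j] = S[j, i] = self._overlap_element(i, j)
        return S * np.outer(self._norms, self._norms)

    def kinetic(self) -> np.ndarray:
        T = np.empty((self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1):
                T[i, j] = T[j, i] = self._kinetic_element(i, j)
        return T * np.outer(self._norms, self._norms)

    def _kinetic_element(self, i: int, j: int) -> float:
        A, B = self._centers[i], self._centers[j]
        la, lb = self._powers[i], self._powers[j]
        val = 0.0
        for a, ca in zip(self._alphas[i], self._coefs[i]):
            for b, cb in zip(self._alphas[j], self._coefs[j]):
                p = a + b
                pref = ca * cb * (np.pi / p) ** 1.5
                S = []  # per-dimension overlap factors E[l1, l2 + shift, 0]
                for d in range(3):
                    E = hermite_expansion(la[d], lb[d] + 2, a, b, A[d] - B[d])
                    S.append(E[la[d], :, 0])
                tdim = []
                for d in range(3):
                    l2 = lb[d]
                    t = b * (2 * l2 + 1) * S[d][l2] - 2.0 * b * b * S[d][l2 + 2]
                    if l2 >= 2:
                        t -= 0.5 * l2 * (l2 - 1) * S[d][l2 - 2]
                    tdim.append(t)
                s0 = [S[d][lb[d]] for d in range(3)]
                val += pref * (
                    tdim[0] * s0[1] * s0[2]
                    + s0[0] * tdim[1] * s0[2]
                    + s0[0] * s0[1] * tdim[2]
                )
        return val

    def point_charge_potential(self, charges, positions_bohr) -> np.ndarray:
        """Matrix of -sum_k q_k * (mu | 1/|r - R_k| | nu).

        With positive nuclear charges this is the nuclear-attraction matrix.
        """
        positions = np.atleast_2d(np.asarray(positions_bohr, dtype=float))
        charges = np.asarray(charges, dtype=float)
        V = np.zeros((self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1):
                val = 0.0
                for pr in self._pairs(i, j):
                    pref = pr.coef * 2.0 * np.pi / pr.p
                    for q, C in zip(charges, positions):
                        R = hermite_coulomb(*pr.lab, pr.p, pr.P - C)
                        val -= pref * q * self._hermite_sum_R(pr, R)
                V[i, j] = V[j, i] = val
        return V * np.outer(self._norms, self._norms)

    def _hermite_sum_R(self, pr: _Pair, R: np.ndarray) -> float:
        Ex, Ey, Ez = pr.Ex, pr.Ey, pr.Ez
        return float(np.einsum("t,u,v,tuv->", Ex, Ey, Ez, R[: len(Ex), : len(Ey), : len(Ez)]))

    def potential_and_field_integrals(self, points_bohr: np.ndarray):
        """For each point C: matrices (mu|1/|r-C||nu) and its -d/dC gradient.

        Returns (P, G) with shapes (npts, n, n) and (npts, 3, n, n);
        ``G[k, x]`` is d/dC_x of ``P[k]`` (note: the *derivative*, no sign).
        """
        points = np.atleast_2d(np.asarray(points_bohr, dtype=float))
        npts = len(points)
        P = np.zeros((npts, self.n, self.n))
        G = np.zeros((npts, 3, self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1):
                for pr in self._pairs(i, j):
                    pref = pr.coef * 2.0 * np.pi / pr.p
                    tmax, umax, vmax = pr.lab
                    for k, C in enumerate(points):
                        R = hermite_coulomb(tmax + 1, umax + 1, vmax + 1, pr.p, pr.P - C)
                        val = pref * self._hermite_sum_R(pr, R)
                        P[k, i, j] += val
                        # dR_{tuv}/dC_x = -R_{t+1,u,v}
                        lx, ly, lz = len(pr.Ex), len(pr.Ey), len(pr.Ez)
                        gx = -np.einsum(
                            "t,u,v,tuv->", pr.Ex, pr.Ey, pr.Ez, R[1 : lx + 1, :ly, :lz]
                        )
                        gy = -np.einsum(
                            "t,u,v,tuv->", pr.Ex, pr.Ey, pr.Ez, R[:lx, 1 : ly + 1, :lz]
                        )
                        gz = -np.einsum(
                            "t,u,v,tuv->", pr.Ex, pr.Ey, pr.Ez, R[:lx, :ly, 1 : lz + 1]
                        )
                        G[k, :, i, j] += pref * np.array([gx, gy, gz])
        for k in range(npts):
            P[k] += np.tril(P[k], -1).T
            P[k] *= np.outer(self._norms, self._norms)
            for x in range(3):
                G[k, x] += np.tril(G[k, x], -1).T
                G[k, x] *= np.outer(self._norms, self._norms)
        return P, G

    def dipole(self) -> np.ndarray:
        """Dipole-moment integrals (mu|r|nu) about the origin, shape (3, n, n)."""
        M = np.zeros((3, self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1):
                acc = np.zeros(3)
                for pr in self._pairs(i, j):
                    pref = pr.coef * (np.pi / pr.p) ** 1.5
                    e0 = np.array([pr.Ex[0], pr.Ey[0], pr.Ez[0]])
                    e1 = np.array(
                        [
                            pr.Ex[1] if len(pr.Ex) > 1 else 0.0,
                            pr.Ey[1] if len(pr.Ey) > 1 else 0.0,
                            pr.Ez[1] if len(pr.Ez) > 1 else 0.0,
                        ]
                    )
                    for d in range(3):
                        others = [e0[k] for k in range(3) if k != d]
                        acc[d] += pref * (e1[d] + pr.P[d] * e0[d]) * others[0] * others[1]
                M[:, i, j] = M[:, j, i] = acc
        return M * np.outer(self._norms, self._norms)

    # -- two-electron integrals ------------------------------------------

    def eri(self) -> np.ndarray:
        """Full (mu nu | la si) tensor with 8-fold permutational symmetry."""
        n = self.n
        out = np.zeros((n, n, n, n))
        pair_index = [(i, j) for i in range(n) for j in range(i + 1)]
        for a, (i, j) in enumerate(pair_index):
            for b in range(a + 1):
                k, l = pair_index[b]
                val = self._eri_element(i, j, k, l)
                for (p, q) in ((i, j), (j, i)):
                    for (r, s) in ((k, l), (l, k)):
                        out[p, q, r, s] = val
                        out[r, s, p, q] = val
        norms = self._norms
        out *= norms[:, None, None, None]
        out *= norms[None, :, None, None]
        out *= norms[None, None, :, None]
        out *= norms[None, None, None, :]
        return out

    def _eri_element(self, i: int, j: int, k: int, l: int) -> float:
        val = 0.0
        for pr1 in self._pairs(i, j):
            E1 = np.einsum("t,u,v->tuv", pr1.Ex, pr1.Ey, pr1.Ez)
            for pr2 in self._pairs(k, l):
                p, q = pr1.p, pr2.p
                alpha = p * q / (p + q)
                pref = (
                    pr1.coef
                    * pr2.coef
                    * 2.0
                    * np.pi**2.5
                    / (p * q * np.sqrt(p + q))
                )
                R = hermite_coulomb(
                    pr1.lab[0] + pr2.lab[0],
                    pr1.lab[1] + pr2.lab[1],
                    pr1.lab[2] + pr2.lab[2],
                    alpha,
                    pr1.P - pr2.P,
                )
                acc = 0.0
                for t2 in range(pr2.lab[0] + 1):
                    for u2 in range(pr2.lab[1] + 1):
                        for v2 in range(pr2.lab[2] + 1):
                            e2 = pr2.Ex[t2] * pr2.Ey[u2] * pr2.Ez[v2]
                            if e2 == 0.0:
                                continue
                            sign = -1.0 if (t2 + u2 + v2) % 2 else 1.0
                            block = R[
                                t2 : t2 + pr1.lab[0] + 1,
                                u2 : u2 + pr1.lab[1] + 1,
                                v2 : v2 + pr1.lab[2] + 1,
                            ]
                            acc += sign * e2 * float(np.sum(E1 * block))
                val += pref * acc
        return val
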