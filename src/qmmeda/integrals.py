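"""Gaussian integrals over contracted cartesian s/p shells.

McMurchie–Davidson scheme: Hermite expansion coefficients E_t^{ij} for
overlap/kinetic/moment integrals, Hermite Coulomb tensor R_{tuv} with the
Boys function for nuclear-attraction, point-charge and electron-repulsion
integrals.  The hot kernels are numba-compiled and fully iterative
(dynamic-programming tables, no recursion); problem sizes here are a few
tens of AOs, so the one-off compilation dominates the first call.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["AOBasis", "build_ao_basis"]

_DFACT = np.array([1.0, 1.0, 3.0, 15.0, 105.0])  # (2n-1)!! for n = 0..4

# Max 1D angular momentum appearing in any E-table: p function shifted by +2
# for the kinetic-energy formula.
_EMAX = 4  # indices 0..3
_TMAX = 2 * _EMAX  # Hermite order bound


@njit(cache=True)
def _e_table(imax, jmax, Qx, a, b, tab):
    """Fill tab[i, j, t] with Hermite expansion coefficients E_t^{ij}.

    Valid for 0 <= i <= imax, 0 <= j <= jmax, 0 <= t <= i + j.  Entries
    outside that triangle are never read (reads are index-guarded), so
    the scratch array is not cleared between calls.
    """
    p = a + b
    q = a * b / p
    one2p = 1.0 / (2.0 * p)
    tab[0, 0, 0] = math.exp(-q * Qx * Qx)
    # build up i at j = 0; E_t^{i0} = 0 for t > i
    for i in range(imax):
        for t in range(i + 2):
            val = 0.0
            if t > 0:
                val += one2p * tab[i, 0, t - 1]
            if t <= i:
                val -= (q * Qx / a) * tab[i, 0, t]
            if t + 1 <= i:
                val += (t + 1.0) * tab[i, 0, t + 1]
            tab[i + 1, 0, t] = val
    # build up j for every i; E_t^{ij} = 0 for t > i + j
    for i in range(imax + 1):
        for j in range(jmax):
            for t in range(i + j + 2):
                val = 0.0
                if t > 0:
                    val += one2p * tab[i, j, t - 1]
                if t <= i + j:
                    val += (q * Qx / b) * tab[i, j, t]
                if t + 1 <= i + j:
                    val += (t + 1.0) * tab[i, j, t + 1]
                tab[i, j + 1, t] = val


@njit(cache=True)
def _boys(mmax, x, out):
    """Fill out[0..mmax] with Boys functions F_m(x)."""
    if x < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if x > 35.0:
        # asymptotic F0, stable upward recursion at large x
        out[0] = 0.5 * math.sqrt(math.pi / x) * math.erf(math.sqrt(x))
        ex = math.exp(-x)
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - ex) / (2.0 * x)
        return
    # series for F_mmax, then stable downward recursion
    term = 1.0 / (2.0 * mmax + 1.0)
    total = term
    k = 0
    while term > 1e-17 * total and k < 300:
        term *= 2.0 * x / (2.0 * mmax + 2.0 * k + 3.0)
        total += term
        k += 1
    ex = math.exp(-x)
    out[mmax] = ex * total
    for m in range(mmax, 0, -1):
        out[m - 1] = (2.0 * x * out[m] + ex) / (2.0 * m - 1.0)


@njit(cache=True)
def _r_table(L, p, PCx, PCy, PCz, boys, R):
    """Fill R[n, t, u, v] Hermite Coulomb auxiliaries for t+u+v+n <= L."""
    _boys(L, p * (PCx * PCx + PCy * PCy + PCz * PCz), boys)
    # every entry with t+u+v+n <= L is written before being read; stale
    # entries outside that region are never consumed
    for n in range(L, -1, -1):
        R[n, 0, 0, 0] = ((-2.0 * p) ** n) * boys[n]
    for n in range(L - 1, -1, -1):
        for order in range(1, L - n + 1):
            for t in range(order + 1):
                for u in range(order - t + 1):
                    v = order - t - u
                    val = 0.0
                    if t > 0:
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                        val += PCx * R[n + 1, t - 1, u, v]
                    elif u > 0:
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                        val += PCy * R[n + 1, t, u - 1, v]
                    else:
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                        val += PCz * R[n + 1, t, u, v - 1]
                    R[n, t, u, v] = val


@njit(cache=True)
def _prim_overlap(tabx, taby, tabz, p, la, lb, lc, ma, mb, mc):
    pre = (math.pi / p) ** 1.5
    return pre * tabx[la, ma, 0] * taby[lb, mb, 0] * tabz[lc, mc, 0]


@njit(cache=True)
def _prim_kinetic(tabx, taby, tabz, p, b, la, lb, lc, ma, mb, mc):
    # Kinetic energy via overlaps with shifted angular momentum on the ket.
    term = b * (2.0 * (ma + mb + mc) + 3.0) * _prim_overlap(
        tabx, taby, tabz, p, la, lb, lc, ma, mb, mc)
    term += -2.0 * b * b * (
        _prim_overlap(tabx, taby, tabz, p, la, lb, lc, ma + 2, mb, mc)
        + _prim_overlap(tabx, taby, tabz, p, la, lb, lc, ma, mb + 2, mc)
        + _prim_overlap(tabx, taby, tabz, p, la, lb, lc, ma, mb, mc + 2))
    if ma > 1:
        term -= 0.5 * ma * (ma - 1) * _prim_overlap(
            tabx, taby, tabz, p, la, lb, lc, ma - 2, mb, mc)
    if mb > 1:
        term -= 0.5 * mb * (mb - 1) * _prim_overlap(
            tabx, taby, tabz, p, la, lb, lc, ma, mb - 2, mc)
    if mc > 1:
        term -= 0.5 * mc * (mc - 1) * _prim_overlap(
            tabx, taby, tabz, p, la, lb, lc, ma, mb, mc - 2)
    return term


@njit(cache=True)
def _kernel_overlap_kinetic(lv, centers, nprim, exps, coefs):
    nao = lv.shape[0]
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    tabx = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    taby = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    tabz = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    for mu in range(nao):
        la, lb, lc = lv[mu, 0], lv[mu, 1], lv[mu, 2]
        Ax, Ay, Az = centers[mu, 0], centers[mu, 1], centers[mu, 2]
        for nu in range(mu + 1):
            ma, mb, mc = lv[nu, 0], lv[nu, 1], lv[nu, 2]
            Bx, By, Bz = centers[nu, 0], centers[nu, 1], centers[nu, 2]
            s = 0.0
            t = 0.0
            for ip in range(nprim[mu]):
                a = exps[mu, ip]
                ca = coefs[mu, ip]
                for jp in range(nprim[nu]):
                    b = exps[nu, jp]
                    cb = coefs[nu, jp]
                    p = a + b
                    _e_table(la, ma + 2, Ax - Bx, a, b, tabx)
                    _e_table(lb, mb + 2, Ay - By, a, b, taby)
                    _e_table(lc, mc + 2, Az - Bz, a, b, tabz)
                    s += ca * cb * _prim_overlap(
                        tabx, taby, tabz, p, la, lb, lc, ma, mb, mc)
                    t += ca * cb * _prim_kinetic(
                        tabx, taby, tabz, p, b, la, lb, lc, ma, mb, mc)
            S[mu, nu] = s
            S[nu, mu] = s
            T[mu, nu] = t
            T[nu, mu] = t
    return S, T


@njit(cache=True)
def _pair_tables(lv, centers, nprim, exps):
    """Per-AO-pair, per-primitive-pair Hermite data.

    Returns E[mu, nu, p1, p2, dim, t] (expansion coefficients up to
    t = l_mu + l_nu per cartesian direction) and the Gaussian product
    centers P[mu, nu, p1, p2, dim].
    """
    nao = lv.shape[0]
    maxp = exps.shape[1]
    E = np.zeros((nao, nao, maxp, maxp, 3, 3))
    P = np.zeros((nao, nao, maxp, maxp, 3))
    tab = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    for mu in range(nao):
        for nu in range(nao):
            for p1 in range(nprim[mu]):
                a = exps[mu, p1]
                for p2 in range(nprim[nu]):
                    b = exps[nu, p2]
                    p = a + b
                    for dim in range(3):
                        la = lv[mu, dim]
                        ma = lv[nu, dim]
                        _e_table(la, ma, centers[mu, dim] - centers[nu, dim],
                                 a, b, tab)
                        for t in range(la + ma + 1):
                            E[mu, nu, p1, p2, dim, t] = tab[la, ma, t]
                        P[mu, nu, p1, p2, dim] = (
                            a * centers[mu, dim] + b * centers[nu, dim]) / p
    return E, P


@njit(cache=True)
def _kernel_potential(lv, centers, nprim, exps, coefs, Epair, Ppair,
                      points, charges):
    """V_{mu nu} = sum_i q_i * <mu| 1/|r - R_i| |nu>  (positive-q convention)."""
    nao = lv.shape[0]
    npt = points.shape[0]
    V = np.zeros((nao, nao))
    boys = np.zeros(_TMAX + 2)
    R = np.zeros((_TMAX + 2, _TMAX + 2, _TMAX + 2, _TMAX + 2))
    for mu in range(nao):
        la, lb, lc = lv[mu, 0], lv[mu, 1], lv[mu, 2]
        for nu in range(mu + 1):
            ma, mb, mc = lv[nu, 0], lv[nu, 1], lv[nu, 2]
            L = la + lb + lc + ma + mb + mc
            val = 0.0
            for ip in range(nprim[mu]):
                a = exps[mu, ip]
                ca = coefs[mu, ip]
                for jp in range(nprim[nu]):
                    b = exps[nu, jp]
                    cb = coefs[nu, jp]
                    p = a + b
                    Px = Ppair[mu, nu, ip, jp, 0]
                    Py = Ppair[mu, nu, ip, jp, 1]
                    Pz = Ppair[mu, nu, ip, jp, 2]
                    pre = 2.0 * math.pi / p * ca * cb
                    for ic in range(npt):
                        _r_table(L, p, Px - points[ic, 0],
                                 Py - points[ic, 1], Pz - points[ic, 2],
                                 boys, R)
                        acc = 0.0
                        for t in range(la + ma + 1):
                            et = Epair[mu, nu, ip, jp, 0, t]
                            for u in range(lb + mb + 1):
                                eu = Epair[mu, nu, ip, jp, 1, u]
                                for v in range(lc + mc + 1):
                                    acc += (et * eu
                                            * Epair[mu, nu, ip, jp, 2, v]
                                            * R[0, t, u, v])
                        val += pre * charges[ic] * acc
            V[mu, nu] = val
            V[nu, mu] = val
    return V


@njit(cache=True)
def _kernel_dipole(lv, centers, nprim, exps, coefs, origin):
    """Electron position integrals <mu| r_k - origin_k |nu>, k = x,y,z."""
    nao = lv.shape[0]
    D = np.zeros((3, nao, nao))
    tabx = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    taby = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    tabz = np.zeros((_EMAX + 1, _EMAX + 1, _TMAX + 2))
    for mu in range(nao):
        la, lb, lc = lv[mu, 0], lv[mu, 1], lv[mu, 2]
        Ax, Ay, Az = centers[mu, 0], centers[mu, 1], centers[mu, 2]
        for nu in range(mu + 1):
            ma, mb, mc = lv[nu, 0], lv[nu, 1], lv[nu, 2]
            Bx, By, Bz = centers[nu, 0], centers[nu, 1], centers[nu, 2]
            dx = 0.0
            dy = 0.0
            dz = 0.0
            for ip in range(nprim[mu]):
                a = exps[mu, ip]
                ca = coefs[mu, ip]
                for jp in range(nprim[nu]):
                    b = exps[nu, jp]
                    cb = coefs[nu, jp]
                    p = a + b
                    pre = ca * cb * (math.pi / p) ** 1.5
                    Px = (a * Ax + b * Bx) / p
                    Py = (a * Ay + b * By) / p
                    Pz = (a * Az + b * Bz) / p
                    _e_table(la, ma, Ax - Bx, a, b, tabx)
                    _e_table(lb, mb, Ay - By, a, b, taby)
                    _e_table(lc, mc, Az - Bz, a, b, tabz)
                    sx0 = tabx[la, ma, 0]
                    sy0 = taby[lb, mb, 0]
                    sz0 = tabz[lc, mc, 0]
                    sx1 = (tabx[la, ma, 1] if la + ma >= 1 else 0.0) \
                        + (Px - origin[0]) * sx0
                    sy1 = (taby[lb, mb, 1] if lb + mb >= 1 else 0.0) \
                        + (Py - origin[1]) * sy0
                    sz1 = (tabz[lc, mc, 1] if lc + mc >= 1 else 0.0) \
                        + (Pz - origin[2]) * sz0
                    dx += pre * sx1 * sy0 * sz0
                    dy += pre * sx0 * sy1 * sz0
                    dz += pre * sx0 * sy0 * sz1
            D[0, mu, nu] = dx
            D[0, nu, mu] = dx
            D[1, mu, nu] = dy
            D[1, nu, mu] = dy
            D[2, mu, nu] = dz
            D[2, nu, mu] = dz
    return D


@njit(cache=True)
def _kernel_eri(lv, centers, nprim, exps, coefs, Epair, Ppair):
    nao = lv.shape[0]
    eri = np.zeros((nao, nao, nao, nao))
    boys = np.zeros(_TMAX + 2)
    R = np.zeros((_TMAX + 2, _TMAX + 2, _TMAX + 2, _TMAX + 2))
    for i in range(nao):
        l1a, l1b, l1c = lv[i, 0], lv[i, 1], lv[i, 2]
        for j in range(i + 1):
            l2a, l2b, l2c = lv[j, 0], lv[j, 1], lv[j, 2]
            for k in range(nao):
                l3a, l3b, l3c = lv[k, 0], lv[k, 1], lv[k, 2]
                for l in range(k + 1):
                    if i * (i + 1) // 2 + j < k * (k + 1) // 2 + l:
                        continue
                    l4a, l4b, l4c = lv[l, 0], lv[l, 1], lv[l, 2]
                    L = (l1a + l1b + l1c + l2a + l2b + l2c
                         + l3a + l3b + l3c + l4a + l4b + l4c)
                    val = 0.0
                    for p1 in range(nprim[i]):
                        a = exps[i, p1]
                        c1 = coefs[i, p1]
                        for p2 in range(nprim[j]):
                            b = exps[j, p2]
                            c2 = coefs[j, p2]
                            p = a + b
                            Px = Ppair[i, j, p1, p2, 0]
                            Py = Ppair[i, j, p1, p2, 1]
                            Pz = Ppair[i, j, p1, p2, 2]
                            for p3 in range(nprim[k]):
                                c = exps[k, p3]
                                c3 = coefs[k, p3]
                                for p4 in range(nprim[l]):
                                    d = exps[l, p4]
                                    c4 = coefs[l, p4]
                                    q = c + d
                                    alpha = p * q / (p + q)
                                    _r_table(L, alpha,
                                             Px - Ppair[k, l, p3, p4, 0],
                                             Py - Ppair[k, l, p3, p4, 1],
                                             Pz - Ppair[k, l, p3, p4, 2],
                                             boys, R)
                                    acc = 0.0
                                    for t in range(l1a + l2a + 1):
                                        e1 = Epair[i, j, p1, p2, 0, t]
                                        for u in range(l1b + l2b + 1):
                                            e2 = Epair[i, j, p1, p2, 1, u]
                                            for v in range(l1c + l2c + 1):
                                                e3 = Epair[i, j, p1, p2, 2, v]
                                                for tau in range(l3a + l4a + 1):
                                                    e4 = Epair[k, l, p3, p4, 0, tau]
                                                    for w in range(l3b + l4b + 1):
                                                        e5 = Epair[k, l, p3, p4, 1, w]
                                                        for ph in range(l3c + l4c + 1):
                                                            e6 = Epair[k, l, p3, p4, 2, ph]
                                                            sg = 1.0 if (tau + w + ph) % 2 == 0 else -1.0
                                                            acc += (e1 * e2 * e3 * e4 * e5 * e6 * sg
                                                                    * R[0, t + tau, u + w, v + ph])
                                    val += (c1 * c2 * c3 * c4 * acc
                                            * 2.0 * math.pi ** 2.5
                                            / (p * q * math.sqrt(p + q)))
                    eri[i, j, k, l] = val
                    eri[j, i, k, l] = val
                    eri[i, j, l, k] = val
                    eri[j, i, l, k] = val
                    eri[k, l, i, j] = val
                    eri[l, k, i, j] = val
                    eri[k, l, j, i] = val
                    eri[l, k, j, i] = val
    return eri


def _primitive_norm(l: np.ndarray, alpha: float) -> float:
    L = int(l.sum())
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = math.sqrt(_DFACT[l[0]] * _DFACT[l[1]] * _DFACT[l[2]])
    return num / den


class AOBasis:
    """Flat contracted cartesian AO basis over a set of centers (bohr)."""

    def __init__(self, lv, centers, nprim, exps, coefs, ao_atom):
        self.lv = np.ascontiguousarray(lv, dtype=np.int64)
        self.centers = np.ascontiguousarray(centers, dtype=np.float64)
        self.nprim = np.ascontiguousarray(nprim, dtype=np.int64)
        self.exps = np.ascontiguousarray(exps, dtype=np.float64)
        self.coefs = np.ascontiguousarray(coefs, dtype=np.float64)
        self.ao_atom = np.asarray(ao_atom, dtype=np.int64)  # AO -> atom index
        self.nao = self.lv.shape[0]
        self._pairs = None

    def _pair_data(self):
        if self._pairs is None:
            self._pairs = _pair_tables(
                self.lv, self.centers, self.nprim, self.exps)
        return self._pairs

    def overlap_kinetic(self):
        return _kernel_overlap_kinetic(
            self.lv, self.centers, self.nprim, self.exps, self.coefs)

    def potential(self, points_bohr, charges):
        """AO matrix of sum_i q_i / |r - R_i| (positive-q convention)."""
        pts = np.ascontiguousarray(
            np.atleast_2d(np.asarray(points_bohr, dtype=np.float64)))
        qs = np.ascontiguousarray(
            np.atleast_1d(np.asarray(charges, dtype=np.float64)))
        if pts.shape[0] == 0 or qs.shape[0] == 0 or pts.size == 0:
            return np.zeros((self.nao, self.nao))
        E, P = self._pair_data()
        return _kernel_potential(
            self.lv, self.centers, self.nprim, self.exps, self.coefs,
            E, P, pts, qs)

    def dipole(self, origin_bohr=None):
        origin = np.zeros(3) if origin_bohr is None else \
            np.asarray(origin_bohr, dtype=np.float64)
        return _kernel_dipole(
            self.lv, self.centers, self.nprim, self.exps, self.coefs, origin)

    def eri(self):
        E, P = self._pair_data()
        return _kernel_eri(
            self.lv, self.centers, self.nprim, self.exps, self.coefs, E, P)


_P_LVECS = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int64)


def build_ao_basis(elements, positions_bohr, shells_by_element) -> AOBasis:
    """Assemble the flat AO arrays for a list of centers.

    ``shells_by_element`` maps an element symbol to its shell list
    (l, exponents, coefficients); contraction coefficients are scaled so
    every contracted AO is normalized to unit self-overlap.
    """
    lv, centers, nprim, exps, coefs, ao_atom = [], [], [], [], [], []
    maxp = max(len(sh[1]) for shs in shells_by_element.values() for sh in shs)
    for iatom, (el, pos) in enumerate(zip(elements, positions_bohr)):
        for l, alphas, cs in shells_by_element[el]:
            if l == 0:
                lvecs = [np.zeros(3, dtype=np.int64)]
            elif l == 1:
                lvecs = list(_P_LVECS)
            else:  # pragma: no cover - only s/p shells are shipped
                raise ValueError(f"unsupported angular momentum l={l}")
            for lvec in lvecs:
                c = np.array([ci * _primitive_norm(lvec, ai)
                              for ai, ci in zip(alphas, cs)])
                # contracted normalization
                p_sum = 0.0
                for ai, ci in zip(alphas, c):
                    for aj, cj in zip(alphas, c):
                        p = ai + aj
                        s = (np.pi / p) ** 1.5 / (2.0 * p) ** int(lvec.sum())
                        s *= _DFACT[lvec[0]] * _DFACT[lvec[1]] * _DFACT[lvec[2]]
                        p_sum += ci * cj * s
                c /= math.sqrt(p_sum)
                lv.append(lvec)
                centers.append(np.asarray(pos, dtype=float))
                nprim.append(len(alphas))
                row_e = np.zeros(maxp)
                row_c = np.zeros(maxp)
                row_e[: len(alphas)] = alphas
                row_c[: len(alphas)] = c
                exps.append(row_e)
                coefs.append(row_c)
                ao_atom.append(iatom)
    return AOBasis(np.array(lv), np.array(centers), np.array(nprim),
                   np.array(exps), np.array(coefs), np.array(ao_atom))
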