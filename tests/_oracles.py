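"""Independent oracles shared by the measurement and acceptance tests."""

import numpy as np
from scipy.optimize import minimize


def unit_cube_triangles(origin=(0.0, 0.0, 0.0)):
    """12 outward-oriented triangles of the unit cube at ``origin``."""
    o = np.asarray(origin, dtype=float)
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                  for z in (0, 1)], dtype=float) + o
    quads = [  # corner ids per face, counter-clockwise seen from outside
        (0, 1, 3, 2), (4, 6, 7, 5),     # x = 0, x = 1
        (0, 4, 5, 1), (2, 3, 7, 6),     # y = 0, y = 1
        (0, 2, 6, 4), (1, 5, 7, 3),     # z = 0, z = 1
    ]
    tris = []
    for a, b, c, d in quads:
        tris.append([v[a], v[b], v[c]])
        tris.append([v[a], v[c], v[d]])
    return np.array(tris)


def voxel_volume(triangles, h=0.05):
    """Brute-force volume by parity ray casting on a voxel-midpoint grid."""
    tri = np.asarray(triangles, dtype=float)
    lo = tri.reshape(-1, 3).min(axis=0)
    hi = tri.reshape(-1, 3).max(axis=0)
    # irrational offsets keep rays off triangle edges and diagonals
    xs = np.arange(lo[0] + 0.287119 * h, hi[0], h)
    ys = np.arange(lo[1] + 0.413562 * h, hi[1], h)
    inside = 0.0
    for x in xs:
        for y in ys:
            zs = []
            for a, b, c in tri:
                d = np.array([b[:2] - a[:2], c[:2] - a[:2]]).T
                det = np.linalg.det(d)
                if abs(det) < 1e-12:
                    continue
                u, v = np.linalg.solve(d, np.array([x, y]) - a[:2])
                if u >= 0 and v >= 0 and u + v <= 1:
                    zs.append(a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2]))
            zs = sorted(zs)
            for z0, z1 in zip(zs[::2], zs[1::2]):
                inside += (z1 - z0) * h * h
    return inside


def single_cube_probe_oracle(delta_P, prestrain=1.2, k=1.0):
    """Closed-form pressure probe on a single pre-strained unit cube.

    By octahedral symmetry the equilibrium of the released cube lies in a
    two-parameter family: vertices at (+-v, +-v, +-v) and face centres at
    distance w from the centre along each axis.  The spring energy, the
    holding-force work and the enclosed volume have closed forms in (v, w);
    minimizing over the two parameters reproduces the probe exactly.
    """
    L0f, L0e = np.sqrt(2.0) / 2.0, 1.0
    v0 = w0 = prestrain / 2.0

    def U(v, w):
        Lf = np.sqrt((w - v) ** 2 + 2 * v ** 2)
        Le = 2 * v
        return 24 * 0.5 * k * max(Lf - L0f, 0.0) ** 2 \
            + 12 * 0.5 * k * max(Le - L0e, 0.0) ** 2

    h = 1e-7
    dUdv = (U(v0 + h, w0) - U(v0 - h, w0)) / (2 * h)
    dUdw = (U(v0, w0 + h) - U(v0, w0 - h)) / (2 * h)

    def V(v, w):
        return 8 * v ** 3 + 8 * v ** 2 * (w - v)

    def G(x):
        v, w = x
        work = dUdv * (v - v0) + dUdw * (w - w0)
        return U(v, w) - work - delta_P * V(v, w)   # applied P = -delta_P

    res = minimize(G, [v0, w0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-15})
    v, w = res.x
    V0, V1 = V(v0, w0), V(v, w)
    return delta_P / ((V1 - V0) / V0)


def intact_lattice_affine_modulus(net, prestrain):
    """Analytic uniform-expansion bulk modulus of an intact cubic block.

    Along the affine family x -> lambda*x the spring energy is
    U = C (lambda-1)^2 / 2 with C = sum k L0^2 (extension energy form).  The
    probe freezes the boundary reactions as constant forces before adding the
    pressure increment, so the uniform-expansion stiffness it sees is
    K = C / (9 V_built lambda0); per unit cell C/V = 9k, giving the
    infinite-lattice value k/lambda0.  Finite blocks deviate by O(1/n)
    surface terms.
    """
    C = float(np.sum(net.spring_k * net.spring_L0 ** 2))
    V_built = net.box_volume / prestrain ** 3
    return C / (9.0 * V_built * prestrain)
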