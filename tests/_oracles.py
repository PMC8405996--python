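"""Independent oracle implementations used only by the tests.

These deliberately share no code with the package: the superposition oracle
uses Horn's quaternion method (the package uses SVD Kabsch), and the
trimmed-mean flag oracle works by explicit sort-trim-flag.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition via Horn's closed-form quaternion method.

    Returns (R, t, rmsd) with reference ≈ R @ mobile + t.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    S = P0.T @ Q0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def brute_force_trim_flags(values: np.ndarray, trim_fraction=0.10, n_sigma=1.5):
    """Sort-trim-flag by hand: returns (trimmed mean, sigma, flagged indices).

    Removes floor(n·trim/2) values from each end of the sorted profile for
    the mean; sigma is the sample sd of the untrimmed profile; flags values
    strictly above trimmed mean + n_sigma·sigma.
    """
    v = np.asarray(values, float)
    order = np.sort(v)
    cut = int(np.floor(len(v) * trim_fraction / 2.0))
    trimmed = order[cut : len(v) - cut] if cut else order
    tm = trimmed.mean()
    sd = v.std(ddof=1)
    flagged = np.flatnonzero(v > tm + n_sigma * sd)
    return tm, sd, flagged
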