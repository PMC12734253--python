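"""Independent, literal transcription of the binary 3-level HGF updates.

Deliberately written in a different style from the package (flat numpy
arrays, one loop, no dataclasses) so it can serve as a brute-force
oracle for the filter.  Keep this file independent of escalearn.hgf.
"""

import numpy as np


def hgf_filter_oracle(
    u,
    kappa=1.0,
    omega2=-3.0,
    omega3=-6.0,
    mu2_0=0.0,
    sigma2_0=0.1,
    mu3_0=1.0,
    sigma3_0=1.0,
):
    u = np.asarray(u, dtype=float)
    T = len(u)
    out = {
        k: np.zeros(T)
        for k in (
            "muhat1",
            "pihat1",
            "muhat2",
            "pihat2",
            "muhat3",
            "pihat3",
            "delta1",
            "delta2",
            "pi2",
            "pi3",
            "mu2",
            "sigma2",
            "mu3",
            "sigma3",
            "psi2",
            "psi3",
            "eps2",
            "eps3",
        )
    }
    mu2, sigma2, mu3, sigma3 = mu2_0, sigma2_0, mu3_0, sigma3_0
    for t in range(T):
        muhat2 = mu2
        muhat3 = mu3
        muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
        v2 = np.exp(kappa * muhat3 + omega2)
        pihat2 = 1.0 / (sigma2 + v2)
        pihat3 = 1.0 / (sigma3 + np.exp(omega3))

        delta1 = u[t] - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        mu2 = muhat2 + delta1 / pi2
        sigma2 = 1.0 / pi2
        delta2 = (sigma2 + (mu2 - muhat2) ** 2) * pihat2 - 1.0
        w2 = v2 * pihat2
        pi3 = pihat3 + 0.5 * kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0:
            raise ArithmeticError(f"oracle pi3 <= 0 at t={t}")
        mu3 = muhat3 + 0.5 * kappa * (w2 / pi3) * delta2
        sigma3 = 1.0 / pi3

        vals = dict(
            muhat1=muhat1,
            pihat1=pihat1,
            muhat2=muhat2,
            pihat2=pihat2,
            muhat3=muhat3,
            pihat3=pihat3,
            delta1=delta1,
            delta2=delta2,
            pi2=pi2,
            pi3=pi3,
            mu2=mu2,
            sigma2=sigma2,
            mu3=mu3,
            sigma3=sigma3,
            psi2=sigma2,
            psi3=pihat2 / pi3,
            eps2=sigma2 * delta1,
            eps3=(pihat2 / pi3) * delta2,
        )
        for k, v in vals.items():
            out[k][t] = v
    return out


def unit_square_sigmoid_oracle(m, beta):
    return m**beta / (m**beta + (1.0 - m) ** beta)


def neg_log_joint_oracle(x, u, choices, prior_mean, prior_var):
    """Independent transcription of the MAP objective (negated)."""
    omega2, omega3, log_beta = x
    beta = np.exp(log_beta)
    tr = hgf_filter_oracle(u, omega2=omega2, omega3=omega3)
    p_go = unit_square_sigmoid_oracle(tr["muhat1"], beta)
    choices = np.asarray(choices)
    p = np.where(choices == 1, p_go, 1.0 - p_go)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(np.log(p)))
    lp = float(
        np.sum(
            -0.5 * np.log(2.0 * np.pi * np.asarray(prior_var))
            - 0.5 * (np.asarray(x) - np.asarray(prior_mean)) ** 2 / np.asarray(prior_var)
        )
    )
    return -(ll + lp)
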