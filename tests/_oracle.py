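"""Independent method-of-lines reference solution.

This is a from-scratch semi-discretization of the lesion model (same
cell-centered radial grid, same age-bin grid, upwind age transport) whose
time integration is delegated to a high-accuracy stiff ODE solver.  It
shares no solver code with the package: the right-hand side below is
written directly from the model equations, so agreement with the IMEX
integrator is a genuine cross-check of both the equations and the time
stepping.
"""

import numpy as np
from scipy.integrate import solve_ivp


def reference_solution(p, dom, n_r, n_a, a_cap, t_end,
                       rtol=1e-8):
    """Integrate the semi-discrete model with BDF; return a dict of the
    physical fields at ``t_end``."""
    dr = dom.r_max / n_r
    r_c = (np.arange(n_r) + 0.5) * dr
    r_e = np.arange(n_r + 1) * dr
    da = a_cap / n_a
    ages = (np.arange(n_a) + 0.5) * da

    # transition kernels at the bin centers
    g_ce = p.kappa_2 * (p.gamma_0 / p.sigma_spread) * (
        np.tanh((ages - p.tau_2) / p.sigma_spread) + 1.0
    )
    g_sa = p.kappa_1 * (p.gamma_0 / p.sigma_spread) * (
        np.tanh((ages - p.tau_1) / p.sigma_spread) + 1.0
    )

    def lap(u, D):
        flux = np.zeros(n_r + 1)
        flux[1:-1] = D * r_e[1:-1] * (u[1:] - u[:-1]) / dr
        return (flux[1:] - flux[:-1]) / (r_c * dr)

    n_scal = 9  # C_U, C_E, S_A, D_N, U, R, M, F, P

    def unpack(y):
        scal = y[: n_scal * n_r].reshape(n_scal, n_r)
        ct = y[n_scal * n_r: n_scal * n_r + n_r * n_a].reshape(n_r, n_a)
        st = y[n_scal * n_r + n_r * n_a:].reshape(n_r, n_a)
        return scal, ct, st

    def rhs(t, y):
        (C_U, C_E, S_A, D_N, U, R, M, F, P), CT, ST = unpack(y)
        hR = R / (p.lambda_R + R)
        hM = M / (p.lambda_M + M)
        hF = F / (p.lambda_F + F)
        hP = P / (p.lambda_P + P)
        H_lo = (p.P_c - P > 0).astype(float)
        H_hi = (P - p.P_c > 0).astype(float)

        ct_tot = CT.sum(axis=1) * da
        st_tot = ST.sum(axis=1) * da

        inflow_ct = p.beta_13 * C_U * hR
        coef = (p.beta_11 * hM + p.beta_12 * hF) * H_lo
        inflow_st = coef * ct_tot

        sink_ct = coef[:, None] + hR[:, None] * g_ce
        sink_st = (p.mu_ST * hF * hM)[:, None] + hF[:, None] * g_sa

        dCT = np.empty_like(CT)
        dCT[:, 0] = (inflow_ct - CT[:, 0]) / da
        dCT[:, 1:] = (CT[:, :-1] - CT[:, 1:]) / da
        dCT -= sink_ct * CT
        dST = np.empty_like(ST)
        dST[:, 0] = (inflow_st - ST[:, 0]) / da
        dST[:, 1:] = (ST[:, :-1] - ST[:, 1:]) / da
        dST -= sink_st * ST

        to_ce = hR * (CT @ (g_ce * da))
        to_sa = hF * (ST @ (g_sa * da))

        dC_U = p.alpha_1 * S_A * hP + p.alpha_2 * H_hi * C_E - inflow_ct
        dC_E = to_ce - p.alpha_2 * H_hi * C_E
        dS_A = to_sa - p.alpha_1 * S_A * hP - p.mu_SA * hF * S_A
        dD_N = -p.mu_DN * D_N
        dU = -p.delta_U * U * hF * H_lo
        dR = lap(R, p.D_R) - p.delta_R * R + p.sigma_R * st_tot
        dM = (lap(M, p.D_M) - p.delta_M * M + p.sigma_M * D_N
              + p.delta_U * U * hF)
        dF = lap(F, p.D_F) - p.delta_F * F + p.sigma_F * st_tot
        dP = (lap(P, p.D_P) - p.delta_P * P
              + p.sigma_P * C_E * hR * p.Lambda / (p.Lambda + F))

        return np.concatenate([
            np.ravel([dC_U, dC_E, dS_A, dD_N, dU, dR, dM, dF, dP]),
            dCT.ravel(), dST.ravel(),
        ])

    inside = r_c < dom.r_impact
    D_N0 = np.where(inside, dom.cell_density_0, 0.0)
    scal0 = np.stack([
        np.where(inside, 0.0, dom.cell_density_0),  # C_U
        np.zeros(n_r),                              # C_E
        np.zeros(n_r),                              # S_A
        D_N0,                                       # D_N
        np.full(n_r, dom.U_0),                      # U
        p.sigma_R * D_N0,                           # R
        np.zeros(n_r),                              # M
        np.zeros(n_r),                              # F
        np.zeros(n_r),                              # P
    ])
    y0 = np.concatenate([scal0.ravel(), np.zeros(2 * n_r * n_a)])

    atol = np.concatenate([
        np.full(n_scal * n_r, 1e-8) * np.maximum(np.abs(scal0).max(), 1.0),
        np.full(2 * n_r * n_a, 1e-3),
    ])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF",
                    rtol=rtol, atol=atol, t_eval=[t_end])
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    (C_U, C_E, S_A, D_N, U, R, M, F, P), CT, ST = unpack(sol.y[:, -1])
    return {
        "C_U": C_U, "C_E": C_E, "S_A": S_A, "D_N": D_N, "U": U,
        "R": R, "M": M, "F": F, "P": P,
        "C_T": CT.sum(axis=1) * da, "S_T": ST.sum(axis=1) * da,
    }
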