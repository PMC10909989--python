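"""Brute-force fixed-step explicit-Euler reference integrator.

Written directly from the printed rate equations on plain floats, with no
shared code with the package's network assembly or adaptive solver, so it
can serve as an independent cross-check of both.
"""

from __future__ import annotations


def euler_states(
    params: dict,
    oligo: float,
    dg2: float,
    times,
    dt: float = 1e-3,
) -> list[tuple[float, ...]]:
    """States at the requested times; species order matches the package.

    ``params`` is the flat table mapping (k_in, kf_1..kf_6, kr_1..kr_4,
    i1, i2, Capacity_G, Capacity_M, Glu_ex).
    """
    k_in = params["k_in"]
    kf1, kr1 = params["kf_1"], params["kr_1"]
    kf2, kr2 = params["kf_2"], params["kr_2"]
    kf3, kr3 = params["kf_3"], params["kr_3"]
    kf4, kr4 = params["kf_4"], params["kr_4"]
    kf5, kf6 = params["kf_5"], params["kf_6"]
    i1, i2 = params["i1"], params["i2"]
    cap_g, cap_m = params["Capacity_G"], params["Capacity_M"]

    stim = 1.0 + oligo * i2 - dg2 * i1
    if stim < 0.0:
        stim = 0.0
    brake = 1.0 - oligo * i2

    glu_ex = params["Glu_ex"]
    glu = pyr = lac = lac_ex = tca = oxpp = cc = 0.0

    out = []
    t = 0.0
    for target in times:
        n_steps = round((target - t) / dt)
        for _ in range(n_steps):
            v1 = k_in * glu_ex * (cap_g - glu)
            v2 = kf1 * glu * stim - kr1 * pyr
            v3 = kf2 * pyr - kr2 * lac
            v4 = kf3 * lac - kr3 * lac_ex
            v5 = kf4 * pyr * (cap_m - tca) - kr4 * tca
            v6 = kf5 * tca * brake
            v7 = kf6 * tca
            glu_ex += dt * (-v1)
            glu += dt * (v1 - v2)
            pyr += dt * (v2 - v3 - v5)
            lac += dt * (v3 - v4)
            lac_ex += dt * v4
            tca += dt * (v5 - v6 - v7)
            oxpp += dt * v6
            cc += dt * v7
        t += n_steps * dt
        out.append((glu_ex, glu, pyr, lac, lac_ex, tca, oxpp, cc))
    return out


def euler_final(params: dict, oligo: float, dg2: float, t_end: float,
                dt: float = 1e-3) -> tuple[float, ...]:
    """Convenience: the state at a single final time."""
    return euler_states(params, oligo, dg2, [t_end], dt)[0]
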