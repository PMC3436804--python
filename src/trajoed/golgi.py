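"""Reference model: secretion control at the trans-Golgi network.

A 9-species mass-action ODE of the PKD / CERT / PI4KIIIbeta / PI4P / DAG /
ceramide regulatory circuit that controls transport-vesicle formation at the
trans-Golgi network.  The interaction topology follows the experimentally
established circuit; quantitative rate constants for it have not been
published, so this is a documented structural reconstruction: activation
fluxes are bilinear mass-action terms, every species carries a linear
degradation self-loop, and basal production rates are fixed at biologically
plausible values so that nominal steady states are O(1)-O(100).

States (active species marked ``a``)::

    PKD, PKDa, CERT, CERTa, PI4K, PI4Ka, PI4P, DAG, CER

Interaction fluxes (free parameters, estimated on the log10 scale):

====  =======================  ==========================================
k1    k1 * DAG * PKD           DAG recruits and activates PKD
k2    k2 * PKDa                PKDa deactivation
k3    k3 * PKDa * PI4K         PKDa activates PI4KIIIbeta
k4    k4 * PI4Ka               PI4Ka deactivation
k5    k5 * PKDa * CERTa        PKDa phosphorylates (deactivates) CERTa
k6    k6 * PI4Ka * pool_pi     PI4P synthesis by active PI4KIIIbeta
k7    k7 * PI4P * CERT         PI4P recruits CERT to the TGN (activation)
k8    k8 * CERTa               basal CERTa deactivation
k9    k9 * CERTa * pool_cer    CERTa-mediated ceramide transfer ER -> TGN
k10   k10 * PKDa * DAG         DAG consumption in vesicle budding
k11   k11 * CER * pool_pc      SM-synthesis turnover: ceramide -> DAG
k12   k12 * PI4P               PI4P hydrolysis (phosphatase)
====  =======================  ==========================================

Measurable outputs: PKDa, PI4Ka, CERTa, total DAG, total ceramide (each
DAG/ceramide pool is a single state here).  PKD, CERT, PI4K and PI4P are
latent.  The perturbable species are PKD, CERT and PI4KIIIbeta, whose basal
synthesis rates can be damped 10-fold (siRNA) or raised 10-fold (vector
overexpression), giving the 3**3 = 27 candidate experiments.

Initial conditions: the unperturbed system is pre-equilibrated to its
steady state at the simulated parameters, then the perturbation input is
applied at t = 0.  SM and PC are not modelled; the PC substrate enters the
SM-synthesis flux as a constant pool.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

from . import _golgi_kernels as _kern
from .ode import (
    ConfigError,
    Experiment,
    OdeModel,
    SimulationError,
    _DivergedState,
    build_catalogue,
    guard_rhs,
)

__all__ = [
    "PARAM_NAMES",
    "FIXED_PARAMS",
    "TRUE_THETA",
    "PERTURBABLE_SPECIES",
    "OUTPUT_NAMES",
    "STATE_NAMES",
    "trans_golgi_model",
    "trans_golgi_catalogue",
]

STATE_NAMES = (
    "PKD", "PKDa", "CERT", "CERTa", "PI4K", "PI4Ka", "PI4P", "DAG", "CER",
)
OUTPUT_NAMES = ("PKDa", "PI4Ka", "CERTa", "DAG", "CER")
PARAM_NAMES = tuple(f"k{i}" for i in range(1, 13))
PERTURBABLE_SPECIES = ("PKD", "CERT", "PI4K")
PERTURBATION_LEVELS = (0.1, 1.0, 10.0)

# 17 fixed parameters: 5 basal productions, 9 degradation self-loops,
# 3 constant substrate pools (ER ceramide, PC, PI); concentration units
# are arbitrary "a.u.", time unit hours.
FIXED_PARAMS: dict[str, float] = {
    "b_PKD": 1.0,
    "b_CERT": 1.0,
    "b_PI4K": 1.0,
    "b_DAG": 0.5,
    "b_CER": 0.5,
    "d_PKD": 0.10,
    "d_PKDa": 0.15,
    "d_CERT": 0.10,
    "d_CERTa": 0.15,
    "d_PI4K": 0.10,
    "d_PI4Ka": 0.15,
    "d_PI4P": 0.30,
    "d_DAG": 0.20,
    "d_CER": 0.20,
    "pool_cer": 10.0,
    "pool_pc": 10.0,
    "pool_pi": 10.0,
}

# Nominal (true) rate constants on the log10 scale: centre of the 4-decade
# log-uniform prior box, chosen once so the unperturbed steady state is
# positive and perturbations produce clear 72-h transients.
TRUE_THETA = np.log10(
    np.array(
        [0.01, 0.1, 0.01, 0.1, 0.01, 0.1, 0.01, 0.1, 0.05, 0.01, 0.005, 0.05]
    )
)

_PRE_EQ_T = 400.0  # hours of unperturbed integration for pre-equilibration
_PRE_EQ_MAX_T = 3200.0


def _rhs(x, u, k, t, fp=FIXED_PARAMS):
    PKD, PKDa, CERT, CERTa, PI4K, PI4Ka, PI4P, DAG, CER = x
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11, k12 = k
    v1 = k1 * DAG * PKD
    v2 = k2 * PKDa
    v3 = k3 * PKDa * PI4K
    v4 = k4 * PI4Ka
    v5 = k5 * PKDa * CERTa
    v6 = k6 * PI4Ka * fp["pool_pi"]
    v7 = k7 * PI4P * CERT
    v8 = k8 * CERTa
    v9 = k9 * CERTa * fp["pool_cer"]
    v10 = k10 * PKDa * DAG
    v11 = k11 * CER * fp["pool_pc"]
    v12 = k12 * PI4P
    return np.array(
        [
            fp["b_PKD"] * u[0] - v1 + v2 - fp["d_PKD"] * PKD,
            v1 - v2 - fp["d_PKDa"] * PKDa,
            fp["b_CERT"] * u[1] - v7 + v5 + v8 - fp["d_CERT"] * CERT,
            v7 - v5 - v8 - fp["d_CERTa"] * CERTa,
            fp["b_PI4K"] * u[2] - v3 + v4 - fp["d_PI4K"] * PI4K,
            v3 - v4 - fp["d_PI4Ka"] * PI4Ka,
            v6 - v12 - fp["d_PI4P"] * PI4P,
            fp["b_DAG"] + v11 - v10 - fp["d_DAG"] * DAG,
            fp["b_CER"] + v9 - v11 - fp["d_CER"] * CER,
        ]
    )


def _jac(x, u, k, t, fp=FIXED_PARAMS):
    PKD, PKDa, CERT, CERTa, PI4K, PI4Ka, PI4P, DAG, CER = x
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11, k12 = k
    J = np.zeros((9, 9))
    # dPKD
    J[0, 0] = -k1 * DAG - fp["d_PKD"]
    J[0, 1] = k2
    J[0, 7] = -k1 * PKD
    # dPKDa
    J[1, 0] = k1 * DAG
    J[1, 1] = -k2 - fp["d_PKDa"]
    J[1, 7] = k1 * PKD
    # dCERT
    J[2, 1] = k5 * CERTa
    J[2, 2] = -k7 * PI4P - fp["d_CERT"]
    J[2, 3] = k5 * PKDa + k8
    J[2, 6] = -k7 * CERT
    # dCERTa
    J[3, 1] = -k5 * CERTa
    J[3, 2] = k7 * PI4P
    J[3, 3] = -k5 * PKDa - k8 - fp["d_CERTa"]
    J[3, 6] = k7 * CERT
    # dPI4K
    J[4, 1] = -k3 * PI4K
    J[4, 4] = -k3 * PKDa - fp["d_PI4K"]
    J[4, 5] = k4
    # dPI4Ka
    J[5, 1] = k3 * PI4K
    J[5, 4] = k3 * PKDa
    J[5, 5] = -k4 - fp["d_PI4Ka"]
    # dPI4P
    J[6, 5] = k6 * fp["pool_pi"]
    J[6, 6] = -k12 - fp["d_PI4P"]
    # dDAG
    J[7, 1] = -k10 * DAG
    J[7, 7] = -k10 * PKDa - fp["d_DAG"]
    J[7, 8] = k11 * fp["pool_pc"]
    # dCER
    J[8, 3] = k9 * fp["pool_cer"]
    J[8, 8] = -k11 * fp["pool_pc"] - fp["d_CER"]
    return J


_OUTPUT_IDX = np.array([1, 5, 3, 7, 8])  # PKDa, PI4Ka, CERTa, DAG, CER


def _output_map(states):
    return np.asarray(states)[..., _OUTPUT_IDX]


def trans_golgi_model(
    fixed_params: dict[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OdeModel:
    """Build the trans-Golgi reference model (9 states, 5 outputs, 12 free
    log10 parameters, 17 fixed basal parameters).

    The returned model's ``initial_state`` pre-equilibrates the unperturbed
    system at the given parameters and caches steady states per parameter
    vector, so simulating many experiments at one theta costs a single
    equilibration.
    """
    fp = dict(FIXED_PARAMS)
    if fixed_params:
        unknown = set(fixed_params) - set(fp)
        if unknown:
            raise ConfigError(f"unknown fixed parameters: {sorted(unknown)}")
        fp.update(fixed_params)

    ss_cache: dict[bytes, np.ndarray] = {}

    def rhs(x, u, k, t):
        return _rhs(x, u, k, t, fp)

    def jac(x, u, k, t):
        return _jac(x, u, k, t, fp)

    def pack(u, k):
        """Bind parameters once per solve (see _golgi_kernels layout)."""
        p = np.empty(29)
        p[0:12] = k
        p[12] = fp["b_PKD"] * u[0]
        p[13] = fp["b_CERT"] * u[1]
        p[14] = fp["b_PI4K"] * u[2]
        p[15] = fp["b_DAG"]
        p[16] = fp["b_CER"]
        p[17:26] = [fp["d_" + n] for n in STATE_NAMES]
        p[26] = fp["pool_cer"]
        p[27] = fp["pool_pc"]
        p[28] = fp["pool_pi"]
        return p

    def prepare_solver(u, k):
        p = pack(np.asarray(u, float), np.asarray(k, float))
        return (
            lambda t, x: _kern.rhs(t, x, p),
            lambda t, x: _kern.jac(t, x, p),
        )

    def initial_state(u, k):
        key = np.asarray(k, float).tobytes()
        x_ss = ss_cache.get(key)
        if x_ss is None:
            x_ss = _pre_equilibrate(pack(np.ones(3), np.asarray(k, float)),
                                    k, fp, rtol, atol)
            if len(ss_cache) > 20000:
                ss_cache.clear()
            ss_cache[key] = x_ss
        return x_ss

    return OdeModel(
        name="trans_golgi",
        state_names=STATE_NAMES,
        output_names=OUTPUT_NAMES,
        param_names=PARAM_NAMES,
        fixed_params=fp,
        vector_field=rhs,
        output_map=_output_map,
        initial_state=initial_state,
        jacobian=jac,
        prepare_solver=prepare_solver,
        rtol=rtol,
        atol=atol,
    )


def _pre_equilibrate(p, k, fp, rtol, atol):
    """Unperturbed steady state by long integration from a crude
    production/degradation balance guess; deterministic given k."""
    x = np.array(
        [
            fp["b_PKD"] / fp["d_PKD"], 1.0,
            fp["b_CERT"] / fp["d_CERT"], 1.0,
            fp["b_PI4K"] / fp["d_PI4K"], 1.0,
            1.0,
            fp["b_DAG"] / fp["d_DAG"],
            fp["b_CER"] / fp["d_CER"],
        ]
    )
    fun = guard_rhs(lambda t, y: _kern.rhs(t, y, p))
    jac = lambda t, y: _kern.jac(t, y, p)
    t_total = 0.0
    horizon = _PRE_EQ_T
    while True:
        try:
            y, info = odeint(
                fun, x, [0.0, horizon], Dfun=jac, tfirst=True,
                rtol=rtol, atol=atol, mxstep=10000, full_output=True,
            )
        except _DivergedState:
            raise SimulationError(
                "pre-equilibration diverged", np.log10(k)
            ) from None
        if info["message"] != "Integration successful." or not np.all(
            np.isfinite(y[-1])
        ):
            raise SimulationError("pre-equilibration failed", np.log10(k))
        x = y[-1]
        t_total += horizon
        resid = np.max(np.abs(_kern.rhs(0.0, x, p)) / (1.0 + np.abs(x)))
        if resid < 1e-8 or t_total >= _PRE_EQ_MAX_T:
            return x


def trans_golgi_catalogue(
    t_end: float = 72.0, n_times: int = 105
) -> list[Experiment]:
    """The 27-experiment catalogue: all perturbation permutations of PKD,
    CERT and PI4KIIIbeta at levels (0.1, 1, 10), all five outputs
    measurable, equidistant ``n_times``-point grid over (0, t_end]."""
    return build_catalogue(
        PERTURBABLE_SPECIES, PERTURBATION_LEVELS, t_end, n_times, OUTPUT_NAMES
    )
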