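"""Independent brute-force oracle: per-cell, per-edge, dictionary-based
evaluation of the network and grid equations, deliberately written without
any vectorization so it shares no code path with the production engine."""

import numpy as np

from fibrogrid.grid import neighbor_coords
from fibrogrid.network import ECM_DIFFUSION_FACTOR


def edge_rate(spec, edge, rates):
    module = {s.name: s.module for s in spec.species}
    if edge.rate_override is not None:
        return edge.rate_override
    if edge.sign == "inhibition":
        return rates.k_inhibition
    if module[edge.target] == "receptor":
        return rates.k_receptor
    return rates.k_activation


def naive_cell_derivatives(spec, x, ext, fb, rates=None):
    """Term-by-term summation over the edge list.

    ``x``, ``ext`` and ``fb`` are name->value dicts; returns a name->rate
    dict.
    """
    rates = rates or spec.rates
    d = {s.name: -rates.k_degradation * x[s.name] for s in spec.species}
    for name in spec.inputs:
        d[name] += rates.k_input * ext.get(name, 0.0)
    for f in spec.feedback_fields:
        if f.feeds is not None:
            d[f.feeds] += rates.k_feedback * fb.get(f.name, 0.0)
    for e in spec.edges:
        term = edge_rate(spec, e, rates)
        for a in e.activators:
            term *= x[a]
        if e.sign == "production":
            d[e.target] += term
        else:
            d[e.target] -= term * x[e.target]
    return d


def naive_step(spec, rates, intra, feedback, ecm, inputs, dt):
    """One clamped Euler step of the full grid, all loops explicit."""
    N = intra.shape[0]
    names = [s.name for s in spec.species]
    fb_names = [f.name for f in spec.feedback_fields]
    new_intra = np.empty_like(intra)
    for i in range(N):
        for j in range(N):
            x = {n: intra[i, j, k] for k, n in enumerate(names)}
            ext = {n: inputs[i, j, k] for k, n in enumerate(spec.inputs)}
            fb = {n: feedback[k, i, j] for k, n in enumerate(fb_names)}
            d = naive_cell_derivatives(spec, x, ext, fb, rates)
            for k, n in enumerate(names):
                new_intra[i, j, k] = min(1.0, max(0.0, x[n] + dt * d[n]))

    def lap(plane, D, i, j):
        total = 0.0
        for (m, n) in neighbor_coords(i, j, N):
            total += plane[m, n] - plane[i, j]
        return D * total

    new_fb = np.empty_like(feedback)
    for k, f in enumerate(spec.feedback_fields):
        D = f.diffusion if f.diffusion is not None else rates.k_diffusion
        lam = f.clearance if f.clearance is not None else rates.k_degradation
        prec = names.index(f.precursor)
        for i in range(N):
            for j in range(N):
                dC = (lap(feedback[k], D, i, j)
                      + rates.k_production * intra[i, j, prec]
                      - lam * feedback[k, i, j])
                new_fb[k, i, j] = min(1.0, max(0.0, feedback[k, i, j] + dt * dC))

    new_ecm = np.empty_like(ecm)
    D_e = ECM_DIFFUSION_FACTOR * rates.k_diffusion
    for m, f in enumerate(spec.ecm_fields):
        prec = names.index(f.precursor)
        for i in range(N):
            for j in range(N):
                dE = (rates.k_production * intra[i, j, prec]
                      - rates.k_degradation * ecm[m, i, j]
                      + lap(ecm[m], D_e, i, j))
                new_ecm[m, i, j] = min(1.0, max(0.0, ecm[m, i, j] + dt * dE))
    return new_intra, new_fb, new_ecm
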