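"""Independent test oracles shared across test modules."""

import numpy as np


def brute_force_invert(curve, rpd, step=0.001):
    """Independent fine-scan inversion with the same conventions:
    sign-change roots first (smallest |delta|, ties negative), otherwise
    the node minimising |C - rpd| (ties toward larger |delta|)."""
    xs = np.arange(-5.0, 5.0 + step / 2, step)
    cs = np.interp(xs, np.asarray(curve.grid.values_mm), curve.array)
    f = cs - rpd
    crossings = []
    for i in range(len(xs) - 1):
        if f[i] == 0.0:
            crossings.append(xs[i])
        elif f[i] * f[i + 1] < 0:
            crossings.append(xs[i] + step * abs(f[i]) / (abs(f[i]) + abs(f[i + 1])))
    if f[-1] == 0.0:
        crossings.append(xs[-1])
    if crossings:
        return min(crossings, key=lambda r: (abs(r), r)), True
    resid = np.abs(f)
    order = sorted(range(len(xs)), key=lambda i: (resid[i], -abs(xs[i]), xs[i]))
    return xs[order[0]], False
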