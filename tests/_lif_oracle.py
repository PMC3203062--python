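"""Brute-force scalar LIF simulator used as an independent oracle.

Written as plain per-neuron Python arithmetic, deliberately independent of
the vectorized implementation it validates: spikes detected after the
update at one step are emitted (and the membrane reset) at the next step,
and the recurrent term at a step uses the spikes emitted at that step.
"""


def scalar_lif(Q, W, theta, x, eta=0.1, n_steps=50, reset=0.0):
    n = len(theta)
    k = len(x)
    u = [reset] * n
    pending = [0] * n
    raster = []
    for _ in range(n_steps):
        emitted = pending[:]
        raster.append(emitted)
        for i in range(n):
            if emitted[i]:
                u[i] = reset
        new_u = []
        for i in range(n):
            drive = sum(Q[i][j] * x[j] for j in range(k))
            recurrent = sum(W[i][m] * emitted[m] for m in range(n))
            new_u.append(u[i] + eta * (drive - recurrent - u[i]))
        u = new_u
        pending = [1 if u[i] > theta[i] else 0 for i in range(n)]
    counts = [sum(step[i] for step in raster) for i in range(n)]
    return raster, counts
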