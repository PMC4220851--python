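"""Independent oracle: the plain stoichiometric predator-prey (KHE) model
and its discrete exponential map, coded directly from the closed-form
equations without reusing any kstoich internals.

This is the l = 0, u = 0 reduction of the full model: tumour cells grow
by the smaller of a logistic carbon rate and a Droop potassium rate,
immune recruitment efficiency degrades below quota theta, and immune
cells only die.  Written against raw floats so it can cross-check the
package's right-hand side and map at random states.
"""

import math


def khe_quota(x, y, K_t, theta, q, mu_m, alpha, closure):
    if closure == "lke":
        return math.inf if x == 0 else (K_t - theta * y) / x
    ratio = mu_m / alpha
    return (q * ratio + K_t - theta * y) / (ratio + x)


def khe_rhs(x, y, *, b, L, K_t, theta, q, mu_m, alpha, e, d, c, a,
            closure="qss"):
    """(dx/dt, dy/dt) of the reduced model, direct transcription."""
    Q = khe_quota(x, y, K_t, theta, q, mu_m, alpha, closure)
    f = c * x / (a + x)
    carbon = 1.0 - x / L
    potassium = 1.0 if math.isinf(Q) else 1.0 - q / Q
    growth = b * (carbon if carbon < potassium else potassium)
    eff = e if (math.isinf(Q) or Q >= theta) else e * Q / theta
    return growth * x - f * y, eff * f * y - d * y


def khe_step(x, y, *, b, L, K_t, theta, q, mu_m, alpha, e, d, c, a,
             closure="qss"):
    """One iterate of the reduced exponential map (frozen per-capita rates)."""
    Q = khe_quota(x, y, K_t, theta, q, mu_m, alpha, closure)
    f = c * x / (a + x)
    P = c / (a + x)                       # f(x)/x for Monod, = c/a at x = 0
    carbon = 1.0 - x / L
    potassium = 1.0 if math.isinf(Q) else 1.0 - q / Q
    growth = b * (carbon if carbon < potassium else potassium)
    eff = e if (math.isinf(Q) or Q >= theta) else e * Q / theta
    gx = growth - P * y
    gy = eff * f - d
    return x * math.exp(gx), y * math.exp(gy)


def full_step_oracle(x, y, *, b, L, K_t, theta, q, mu_m, alpha, e, d, l, u,
                     c, a, closure="qss"):
    """Brute-force arithmetic oracle for the full map (l, u included)."""
    Q = khe_quota(x, y, K_t, theta, q, mu_m, alpha, closure)
    f = c * x / (a + x)
    P = c / (a + x)
    carbon = 1.0 - x / L
    potassium = 1.0 if math.isinf(Q) else 1.0 - q / Q
    growth = b * (carbon if carbon < potassium else potassium)
    eff = e if (math.isinf(Q) or Q >= theta) else e * Q / theta
    gx = growth - P * y
    gy = eff * f - l * x - d + (u / y if y > 0 else 0.0)
    return x * math.exp(gx), y * math.exp(gy)
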