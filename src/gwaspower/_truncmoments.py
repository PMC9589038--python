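"""Numerically stable outer-tail moments of zero-mean normal distributions.

Everything here is an *unconditional* tail moment ``E[g(X) 1{|X| > t}]`` for
``X ~ N(0, v)``.  Working with unconditional moments lets mixture-weighted
conditional expectations be assembled without dividing by tail probabilities
that underflow for thresholds many standard deviations out; the single final
division happens at full mixture scale.

The tail density ratio ``phi(z)/Q(z)`` that appears in conditional forms is
avoided entirely: products like ``Q(z) * E[X^2 | X > t]`` are expanded into
``z*phi(z) + Q(z)`` terms, each computed directly.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _phi(z):
    return _INV_SQRT_2PI * np.exp(-0.5 * np.square(z))


def _two_tails(z):
    """P(|Z| > z) for standard normal Z, stable far into the tail."""
    return special.erfc(np.asarray(z) / _SQRT2)


def tail_mass(v, t):
    """P(|X| > t) for X ~ N(0, v)."""
    return _two_tails(t / np.sqrt(v))


def tail_m2(v, t):
    """E[X^2 1{|X| > t}] for X ~ N(0, v).

    From integration by parts, ``int_z^inf x^2 phi(x) dx = z phi(z) + Q(z)``
    on the standard scale; both tails double the result.
    """
    z = t / np.sqrt(v)
    return v * (2.0 * z * _phi(z) + _two_tails(z))


def tail_m4(v, t):
    """E[X^4 1{|X| > t}] for X ~ N(0, v)."""
    z = t / np.sqrt(v)
    return v * v * (2.0 * (z**3 + 3.0 * z) * _phi(z) + 3.0 * _two_tails(z))


def lower_mean_var(a):
    """Mean and variance of a standard normal truncated to X < a."""
    p = special.ndtr(a)
    if p <= 0.0:
        raise ValueError(f"empty lower tail at threshold {a}")
    mu = -_phi(a) / p
    var = 1.0 - a * _phi(a) / p - mu * mu
    return mu, var


def upper_mean_var(b):
    """Mean and variance of a standard normal truncated to X > b."""
    q = special.ndtr(-b)
    if q <= 0.0:
        raise ValueError(f"empty upper tail at threshold {b}")
    mu = _phi(b) / q
    var = 1.0 + b * _phi(b) / q - mu * mu
    return mu, var
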