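"""Independent straight-line oracles used to cross-check the implementation.

Everything here is deliberately written as direct single-expression /
straight-line re-evaluations of the defining formulas, independent of the
package's code paths (no shared helpers, no reuse of the engine).
"""

import math


# ---- index formulas -------------------------------------------------------

def iaqi_oracle(c, rows):
    """rows: list of (c_low, c_high, i_low, i_high); c assumed in range."""
    for c_lo, c_hi, i_lo, i_hi in rows:
        if c_lo <= c <= c_hi:
            return i_lo + (i_hi - i_lo) * (c - c_lo) / (c_hi - c_lo)
    raise AssertionError("oracle: no bracketing row")


def tci_ratio_oracle(t, v, rh):
    return (t - 14.3) / (1 + 0.0216 * v * (t - 14.3)) + (1 - 0.01 * abs(70.5 - rh))


def tci_additive_oracle(t, v, rh):
    return (t - 14.3) + 0.0216 * v * (t - 14.3) + (1 - 0.01 * abs(70.5 - rh))


def npi_oracle(pairs):
    return sum(p * d for p, d in pairs) / sum(p for p, _ in pairs)


def isum_oracle(panel, standards):
    return sum(c / standards[p] for p, c in panel.items())


# ---- fuzzy engine ---------------------------------------------------------

def mf_oracle(mf, x):
    """Evaluate a membership function from its parameters alone."""
    kind = type(mf).__name__
    if kind == "SigmoidMF":
        return 1.0 / (1.0 + math.exp(-mf.c * (x - mf.a) / mf.b))
    if kind == "GaussianMF":
        return math.exp(-((x - mf.b) ** 2) / (2.0 * mf.sigma**2))
    if kind == "TriangularMF":
        if x == mf.peak:
            return 1.0
        if x <= mf.left or x >= mf.right:
            return 0.0
        if x < mf.peak:
            return (x - mf.left) / (mf.peak - mf.left)
        return (mf.right - x) / (mf.right - mf.peak)
    if kind == "SigmoidDiffMF":
        lo = 1.0 / (1.0 + math.exp(-mf.c * (x - mf.a_left)))
        hi = 1.0 / (1.0 + math.exp(-mf.c * (x - mf.a_right)))
        return max(lo - hi, 0.0)
    raise AssertionError(f"oracle: unknown MF kind {kind}")


def fis_oracle(system, record):
    """Straight-line fuzzify / fire / defuzzify over the system's parameters."""
    variables = {v.name: v for v in system.inputs}
    num = 0.0
    den = 0.0
    for rule in system.rules:
        if system.and_operator == "product":
            strength = 1.0
            for var, label in rule.antecedent:
                v = variables[var]
                x = min(max(record[var], v.universe[0]), v.universe[1])
                strength *= mf_oracle(v.terms[label], x)
        else:
            strength = math.inf
            for var, label in rule.antecedent:
                v = variables[var]
                x = min(max(record[var], v.universe[0]), v.universe[1])
                strength = min(strength, mf_oracle(v.terms[label], x))
        strength *= rule.weight
        if isinstance(rule.consequent, str):
            if system.consequent_levels is not None:
                level = system.consequent_levels[rule.consequent]
            else:
                out_mf = system.output.terms[rule.consequent]
                kind = type(out_mf).__name__
                level = {
                    "SigmoidMF": lambda m: m.a,
                    "GaussianMF": lambda m: m.b,
                    "TriangularMF": lambda m: m.peak,
                    "SigmoidDiffMF": lambda m: 0.5 * (m.a_left + m.a_right),
                }[kind](out_mf)
        else:
            level = float(rule.consequent)
        num += strength * level
        den += strength
    if den <= 0:
        raise ZeroDivisionError("oracle: no rule fired")
    return num / den
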