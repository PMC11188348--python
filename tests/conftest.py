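import numpy as np
import pytest

from urbanhealth import (
    FuzzyRule,
    FuzzySystem,
    FuzzyVariable,
    GaussianMF,
    SigmoidMF,
    TriangularMF,
    build_default_tree,
    builtin_profiles,
    default_breakpoints,
    generate_city,
)
from urbanhealth.assessment import (
    DEFAULT_UNIVERSES,
    AirSample,
    EnvironmentalRecord,
    SoilSample,
    WaterSample,
)
from urbanhealth.indices import ThermalInput


@pytest.fixture(scope="session")
def tables():
    return default_breakpoints()


@pytest.fixture(scope="session")
def tree():
    return build_default_tree()


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def b_batch(profiles):
    """A moderate-size batch from the most-polluted archetype."""
    return generate_city(profiles["B"], 300, seed=20240605)


def make_record(fractions=None, **overrides):
    """Record with each variable at a fraction of its universe (default 0.5)."""
    frac = {v: 0.5 for v in DEFAULT_UNIVERSES}
    if fractions:
        frac.update(fractions)
    val = {
        v: DEFAULT_UNIVERSES[v][0]
        + frac[v] * (DEFAULT_UNIVERSES[v][1] - DEFAULT_UNIVERSES[v][0])
        for v in DEFAULT_UNIVERSES
    }
    val.update(overrides)
    return EnvironmentalRecord(
        site=overrides.get("site", "test"),
        timestamp=overrides.get("timestamp", "2022-06-01T12:00:00"),
        air=AirSample(val["pm25"], val["no2"], val["pm10"], val["o3"]),
        water=WaterSample(val["heavy_metal"], val["dissolved_oxygen"], val["ph"]),
        soil=SoilSample(val["organic_matter"], val["n_p_content"]),
        noise_level=val["noise_level"],
        thermal=ThermalInput(24.0, 2.0, 60.0),
    )


def random_system(rng: np.random.Generator) -> tuple[FuzzySystem, list[dict]]:
    """A random small fuzzy system (<=3 inputs, <=12 rules) plus test points."""
    n_inputs = int(rng.integers(1, 4))
    inputs = []
    for i in range(n_inputs):
        n_terms = int(rng.integers(2, 4))
        terms = {}
        for t in range(n_terms):
            kind = rng.integers(0, 3)
            center = float(rng.uniform(0.1, 0.9))
            if kind == 0:
                terms[f"t{t}"] = SigmoidMF(
                    a=center, c=float(rng.uniform(0.5, 10.0) * rng.choice([-1, 1]))
                )
            elif kind == 1:
                terms[f"t{t}"] = GaussianMF(b=center, sigma=float(rng.uniform(0.05, 0.5)))
            else:
                left = float(rng.uniform(0.0, 0.4))
                peak = left + float(rng.uniform(0.05, 0.4))
                terms[f"t{t}"] = TriangularMF(left=left, peak=peak, right=peak + float(rng.uniform(0.05, 0.4)))
        inputs.append(FuzzyVariable(name=f"x{i}", universe=(0.0, 1.0), terms=terms))
    output = FuzzyVariable(
        name="y",
        universe=(0.0, 1.0),
        terms={
            "lo": GaussianMF(b=0.15, sigma=0.1),
            "mid": GaussianMF(b=0.5, sigma=0.1),
            "hi": GaussianMF(b=0.85, sigma=0.1),
        },
    )
    n_rules = int(rng.integers(1, 13))
    rules = []
    for _ in range(n_rules):
        # guarantee every input is referenced: first rules cover all inputs
        antecedent = tuple(
            (v.name, str(rng.choice(list(v.terms)))) for v in inputs
        )
        rules.append(
            FuzzyRule(
                antecedent=antecedent,
                consequent=str(rng.choice(["lo", "mid", "hi"])),
                weight=float(rng.uniform(0.1, 2.0)),
            )
        )
    system = FuzzySystem(
        inputs=tuple(inputs),
        output=output,
        rules=tuple(rules),
        and_operator=str(rng.choice(["product", "min"])),
    )
    points = [
        {v.name: float(rng.uniform(0.0, 1.0)) for v in inputs} for _ in range(5)
    ]
    return system, points
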