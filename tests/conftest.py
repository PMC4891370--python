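import numpy as np
import pytest
from scipy import stats as sps

from glycotof.chem import ISOTOPES, ElementCounts
from glycotof.features import enumerate_default_features


@pytest.fixture(scope="session")
def feature_list():
    return enumerate_default_features()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160229)


def isotope_pattern_oracle(formula: ElementCounts, coverage: float):
    """Exhaustive enumeration oracle for isotope patterns.

    Enumerates heavy-isotope count vectors per element with exact
    binomial/multinomial probabilities, aggregates by nominal mass
    shift (abundance-weighted mean mass), and truncates/normalizes the
    prefix exactly like the implementation contract: minimal
    nominal-mass prefix with cumulative raw abundance >= coverage,
    abundances renormalized over the returned peaks.

    Independent of the implementation: no convolution, direct summation
    over all isotopologue classes up to a fixed shift bound.
    """
    max_shift = 10
    per_element = []  # list of dict shift -> (prob, prob*mass)
    for el in ("C", "H", "N", "O"):
        n = getattr(formula, el)
        isotopes = ISOTOPES[el]
        base_mass = isotopes[0][0]
        dist: dict[int, tuple[float, float]] = {}
        if n == 0:
            dist[0] = (1.0, 0.0)
        elif len(isotopes) == 2:
            (m0, p0), (m1, p1) = isotopes
            shift1 = round(m1 - m0)
            for k in range(0, min(n, max_shift // shift1) + 1):
                prob = float(sps.binom.pmf(k, n, p1))
                mass = (n - k) * m0 + k * m1
                s = k * shift1
                acc = dist.get(s, (0.0, 0.0))
                dist[s] = (acc[0] + prob, acc[1] + prob * mass)
        else:  # oxygen: three isotopes
            (m0, p0), (m1, p1), (m2, p2) = isotopes
            for k1 in range(0, min(n, max_shift) + 1):
                for k2 in range(0, min(n - k1, max_shift // 2) + 1):
                    s = k1 + 2 * k2
                    if s > max_shift:
                        continue
                    k0 = n - k1 - k2
                    prob = float(
                        np.exp(
                            sps.multinomial.logpmf([k0, k1, k2], n, [p0, p1, p2])
                        )
                    )
                    mass = k0 * m0 + k1 * m1 + k2 * m2
                    acc = dist.get(s, (0.0, 0.0))
                    dist[s] = (acc[0] + prob, acc[1] + prob * mass)
        per_element.append(dist)

    total: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for dist in per_element:
        new: dict[int, tuple[float, float]] = {}
        for s1, (p1_, m1_) in total.items():
            for s2, (p2_, m2_) in dist.items():
                s = s1 + s2
                if s > max_shift:
                    continue
                acc = new.get(s, (0.0, 0.0))
                # m-values carry probability-weighted mass sums
                new[s] = (acc[0] + p1_ * p2_, acc[1] + p1_ * m2_ + m1_ * p2_)
        total = new

    mono = formula.monoisotopic_mass()
    peaks = []
    cum = 0.0
    for s in sorted(total):
        p, pm = total[s]
        if p <= 0:
            continue
        peaks.append((pm / p - mono, p))
        cum += p
        if cum >= coverage - 1e-12:
            break
    return [(off, p / cum) for off, p in peaks]
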