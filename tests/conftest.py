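import random

import pytest

from cglrkit import enumerate_candidates, load_default_patterns
from cglrkit.motif import MotifElement, MotifPattern


@pytest.fixture(scope="session")
def patterns():
    return load_default_patterns()


@pytest.fixture(scope="session")
def active_site(patterns):
    return patterns["active_site"]


@pytest.fixture(scope="session")
def all_candidates():
    return enumerate_candidates()


def random_pattern_and_sequence(rng: random.Random, max_combos: int = 10_000):
    """A random small degenerate pattern plus a sequence to scan.

    Patterns mix fixed residues, inline classes and bounded gaps (never two
    adjacent); sequences occasionally contain non-standard codes so that
    gap-versus-anchor handling is exercised. Total gap combinations stay
    under ``max_combos`` so the exhaustive oracle is cheap.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    while True:
        n_el = rng.randint(2, 5)
        elements = []
        combos = 1
        prev_gap = rng.random() < 0.5  # sometimes forbid a leading gap
        for _ in range(n_el):
            if not prev_gap and rng.random() < 0.4:
                lo = rng.randint(0, 3)
                hi = lo + rng.randint(0, 3)
                combos *= hi - lo + 1
                elements.append(MotifElement("gap", min_len=lo, max_len=hi))
                prev_gap = True
            elif rng.random() < 0.5:
                elements.append(MotifElement("fixed", residue=rng.choice(alphabet)))
                prev_gap = False
            else:
                members = frozenset(rng.sample(alphabet, rng.randint(2, 6)))
                elements.append(MotifElement("class", members=members))
                prev_gap = False
        if combos > max_combos or not any(e.kind != "gap" for e in elements):
            continue
        pattern = MotifPattern(name="random", elements=tuple(elements))
        chars = [rng.choice(alphabet) for _ in range(rng.randint(20, 80))]
        for _ in range(rng.randint(0, 3)):  # sprinkle non-standard codes
            chars[rng.randrange(len(chars))] = rng.choice("BXZ*")
        # seed a few pattern fragments so matches actually occur
        for _ in range(rng.randint(0, 3)):
            frag = []
            for el in elements:
                if el.kind == "gap":
                    frag.extend(
                        rng.choice(alphabet)
                        for _ in range(rng.randint(el.min_len, el.max_len))
                    )
                elif el.kind == "fixed":
                    frag.append(el.residue)
                else:
                    frag.append(rng.choice(sorted(el.members)))
            pos = rng.randrange(len(chars))
            chars[pos:pos] = frag
        return pattern, "".join(chars)
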