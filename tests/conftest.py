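"""Shared fixtures: a small mock reference and a noise-free simulated run."""

from __future__ import annotations

import numpy as np
import pytest

import scatdiet as sd
from scatdiet.simulate import NOISE_FREE


@pytest.fixture(scope="session")
def scheme() -> sd.TagScheme:
    return sd.default_tag_scheme()


@pytest.fixture(scope="session")
def mock_reference():
    """(records, rules) with 6 food + 2 of each nuisance category."""
    return sd.build_mock_reference(
        n_food=6, n_parasite=2, n_contaminant=2, n_unicell=2, seed=11
    )


@pytest.fixture(scope="session")
def small_run(scheme, mock_reference):
    """A noise-free 6-scat x 150-read run with its sheet and truth table."""
    reference, rules = mock_reference
    fwd = list(scheme.forward_tags)
    rev = list(scheme.reverse_tags)
    rows = [
        sd.SampleSheetRow(
            run_id="run1",
            scat_id=f"S{i:02d}",
            fwd_tag=fwd[i % len(fwd)],
            rev_tag=rev[i // len(fwd)],
            population_id="popA",
            sex="F" if i % 2 else "M",
        )
        for i in range(6)
    ]
    communities = sd.make_population([r.scat_id for r in rows], seed=5)
    reads, truth = sd.simulate_run(
        rows, communities, scheme, NOISE_FREE, reference, seed=7,
        n_reads=150, rules=rules,
    )
    return {
        "rows": rows,
        "communities": communities,
        "reads": reads,
        "truth": truth,
        "reference": reference,
        "rules": rules,
    }


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))
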