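import numpy as np
import pytest

from paralogon.align import Alignment, ScoringScheme
from paralogon.simulate import BranchSpec, CassetteSpec, SimulationConfig

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def small_alignment():
    return Alignment(
        rows=[
            ("s1", "YGGFMKR-AC"),
            ("s2", "YGGFLKRQAC"),
            ("s3", "YGGLM--QAC"),
            ("s4", "----MKRQAC"),
        ]
    )


def two_round_config(seed, retention=0.6, n_chromosomes=4, families_per_chromosome=15, species="spA"):
    """One lineage through two whole-genome duplications and one loss round."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        families_per_chromosome=families_per_chromosome,
        tree=BranchSpec(
            name="root",
            events=[
                {"kind": "wgd", "label": "2Ra"},
                {"kind": "wgd", "label": "2Rb"},
                {"kind": "loss", "retention": retention},
            ],
            children=[BranchSpec(name=species)],
        ),
    )


def gene_tree_config(seed, branch_length=0.05, loss_retention=None, sequence_length=200):
    """One family duplicated before a two-sided speciation, plus an outgroup
    lineage that diverged before the duplication."""
    def leaf(name):
        events = []
        if loss_retention is not None:
            events.append({"kind": "loss", "retention": loss_retention})
        return {"name": name, "length": branch_length, "events": events}

    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        families_per_chromosome=1,
        sequence_length=sequence_length,
        tree=BranchSpec.from_dict(
            {
                "name": "origin",
                "length": branch_length,
                "children": [
                    {"name": "outgrp", "length": branch_length},
                    {
                        "name": "ingroup",
                        "events": [{"kind": "wgd", "label": "2Ra"}],
                        "length": branch_length,
                        "children": [
                            {
                                "name": "landside",
                                "length": branch_length,
                                "children": [leaf("t1"), leaf("t2")],
                            },
                            {
                                "name": "waterside",
                                "length": branch_length,
                                "children": [leaf("f1"), leaf("f2")],
                            },
                        ],
                    },
                ],
            }
        ),
    )
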