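import itertools

import pytest

from trialmatch.criteria_miner import Triplet
from trialmatch.eligibility_db import EligibilityDB
from trialmatch.synthetic_corpus import CorpusSpec, base_terminology, generate_corpus
from trialmatch.trial_ingest import parse_trial

#: the per-dimension triplet classes swept by the class-combination fixture
TABLE_CLASSES = ("inclusion", "NA", "exclusion", "NC", None)


@pytest.fixture(scope="session")
def term():
    """The built-in six-category terminology."""
    return base_terminology()


@pytest.fixture(scope="session")
def bundle():
    """A 50-trial seeded corpus with planted ground truth."""
    return generate_corpus(CorpusSpec(seed=11, n_trials=50))


@pytest.fixture(scope="session")
def db(bundle):
    """Eligibility database mined from the 50-trial corpus."""
    return EligibilityDB.build(bundle.trials, bundle.terminology)


@pytest.fixture(scope="session")
def bundle100():
    """Larger corpus for matcher-vs-oracle sweeps."""
    return generate_corpus(CorpusSpec(seed=23, n_trials=100))


@pytest.fixture(scope="session")
def db100(bundle100):
    return EligibilityDB.build(bundle100.trials, bundle100.terminology)


@pytest.fixture(scope="session")
def table_db():
    """One trial per (alteration-class x cancer-class) triplet combination.

    The profile under test holds alteration entry "A" and cancer entry "C";
    every pairing of {inclusion, NA, exclusion, NC, absent} for the two
    dimensions gets its own trial, so category rules can be swept
    exhaustively.
    """
    trials, triplets = [], []
    for i, (ac, cc) in enumerate(itertools.product(TABLE_CLASSES, repeat=2)):
        tid = f"NCT{i:03d}"
        trials.append(parse_trial({"trial_id": tid, "metadata": {}, "passages": []}))
        if ac is not None:
            triplets.append(Triplet("A", ac, tid))
        if cc is not None:
            triplets.append(Triplet("C", cc, tid))
    return EligibilityDB(trials, triplets=triplets)
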