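import pytest

from foldswitch_eval import make_fold_pair


@pytest.fixture(scope="session")
def refs():
    """A 60-residue toy fold-switching protein: helical vs extended over
    residues 21-50, conformers separated by well over 5 A."""
    return make_fold_pair(length=60, region=(21, 50), seed=1)
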