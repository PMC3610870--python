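import numpy as np
import pytest

from nodtx.io_formats import ContigProfile, GenomeSequence, StrandProfiles


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeSequence("c1", seq)


def make_profiles(length=2000, contig="c1", **tracks):
    """Build StrandProfiles from sparse {position: value} dicts.

    tracks keys: starts_plus, starts_minus, coverage_plus, coverage_minus.
    Coverage defaults to the starts track so the coverage >= starts
    invariant holds.
    """
    prof = ContigProfile(length)
    for name, updates in tracks.items():
        arr = getattr(prof, name)
        for pos, val in updates.items():
            arr[pos] = val
    if "coverage_plus" not in tracks:
        prof.coverage_plus = np.maximum(prof.coverage_plus, prof.starts_plus)
    else:
        prof.coverage_plus = np.maximum(prof.coverage_plus, prof.starts_plus)
    prof.coverage_minus = np.maximum(prof.coverage_minus, prof.starts_minus)
    return StrandProfiles({contig: prof})
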