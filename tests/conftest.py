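import numpy as np
import pytest
from hypothesis import settings

from dualeeg.types import MONTAGE_16, ParadigmSpec, Recording

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def montage():
    return list(MONTAGE_16)


@pytest.fixture
def oddball_spec():
    return ParadigmSpec(paradigm_kind="oddball_passive")


def naive_oddball_check(labels, blocks, spec):
    """Independent brute-force validator of every oddball constraint.

    Scans the raw label sequence directly; shares no code with the
    generator.
    """
    assert len(labels) == spec.n_tones
    n_dev = labels.count("deviant")
    assert n_dev == round(spec.n_tones * spec.deviant_fraction)
    per_block = {}
    for lab, b in zip(labels, blocks):
        per_block.setdefault(b, []).append(lab)
    assert sorted(per_block) == list(range(spec.n_blocks))
    for b, labs in per_block.items():
        assert labs.count("deviant") == n_dev // spec.n_blocks
        lead = 0
        for lab in labs:
            if lab != "standard":
                break
            lead += 1
        assert lead >= spec.min_leading_standards, f"block {b} leads with {lead}"
    gap = None
    for lab in labels:
        if lab == "deviant":
            if gap is not None:
                assert spec.min_gap <= gap <= spec.max_gap, f"gap {gap}"
            gap = 0
        elif gap is not None:
            gap += 1


def make_recording(data, rate=129.05, labels=None, events=()):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = list(MONTAGE_16)[: data.shape[0]]
    return Recording(data=data, rate_hz=rate, channel_labels=labels,
                     events=list(events))
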