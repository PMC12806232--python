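import numpy as np
import pytest

from ddievent.data import ENTITY_CLASSES, DrugRecord, EventDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _record(drug_id, smiles, bits_seed):
    r = np.random.default_rng(bits_seed)
    bits = {cls: r.integers(0, 2, size=6).astype(np.uint8)
            for cls in ENTITY_CLASSES}
    return DrugRecord(drug_id, smiles, bits)


@pytest.fixture
def tiny_dataset():
    """Four drugs, two event types, four labeled pairs."""
    drugs = [
        _record("D0", "CCO", 0),
        _record("D1", "CCN", 1),
        _record("D2", "CCC", 2),
        _record("D3", "CO", 3),
    ]
    triples = [(0, 1, 0), (2, 3, 0), (1, 2, 1), (0, 3, 1)]
    return EventDataset(drugs, triples, n_events=2, event_names=[0, 1])
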