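import numpy as np
import pandas as pd
import pytest

from matneo.tables import CountTable


def make_count_table(counts, sample_ids=None, taxon_ids=None, meta=None, **meta_kwargs):
    """Build a CountTable from a 2-D array with default metadata."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i}" for i in range(n_taxa)]
    if sample_ids is None:
        sample_ids = [f"sample_{j}" for j in range(n_samples)]
    if meta is None:
        defaults = {
            "subject_id": [f"subj_{j}" for j in range(n_samples)],
            "role": "neonate",
            "site": "buccal",
            "day": "1",
            "collection_time": list(np.arange(n_samples, dtype=float)),
        }
        defaults.update(meta_kwargs)
        meta = pd.DataFrame(defaults, index=sample_ids)
    df = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    return CountTable(df, meta)


@pytest.fixture
def toy_table():
    return make_count_table([[10, 0, 3], [5, 8, 0], [0, 2, 7]])
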