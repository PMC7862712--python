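import numpy as np
import pytest

from decban.encoding import EmbeddingTable


def make_table(tokens, dimension, seed=0, oov_policy="zero"):
    """Deterministic random embedding table over the given tokens."""
    rng = np.random.default_rng(seed)
    return EmbeddingTable(
        dimension=dimension,
        vectors={t: rng.normal(size=dimension).astype(np.float32)
                 for t in tokens},
        oov_policy=oov_policy,
    )


def all_kmers(k, alphabet="ACGU"):
    import itertools
    return ["".join(p) for p in itertools.product(alphabet, repeat=k)]


@pytest.fixture(scope="session")
def tiny_tables():
    """Full-coverage 7-mer RNA table plus peptide table, 4+3 dims."""
    from decban.encoding import translate_word
    rna_tokens = all_kmers(7)
    pep_tokens = sorted({translate_word(t) for t in rna_tokens})
    return (make_table(rna_tokens, 4, seed=1),
            make_table(pep_tokens, 3, seed=2))
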