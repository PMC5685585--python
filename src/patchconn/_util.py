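import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Wrap a seed into a SeedSequence, passing an existing one through."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
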