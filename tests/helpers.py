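import numpy as np


def attach_reducer(world, patch):
    """Pin the world's first reducer onto a given bulk patch."""
    r = world.reducers[0]
    r.position = np.asarray(patch, dtype=float) + 0.5
    r.attached_patch = tuple(patch)
    r.ticks_attached = 0
    return r
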