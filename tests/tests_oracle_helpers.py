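"""Brute-force helpers shared by oracle-equivalence tests."""

import numpy as np


def brute_force_class_sets(gold, pred, c):
    """(TP, FP, FN) for class c by explicit pixel-set operations."""
    g = {(i, j) for i, j in zip(*np.nonzero(gold == c))}
    p = {(i, j) for i, j in zip(*np.nonzero(pred == c))}
    return len(g & p), len(p - g), len(g - p)
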