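import pytest

import tendonquant as tq


@pytest.fixture(scope="session")
def section():
    """One default synthetic section with its ground truth."""
    config = tq.SynthImageConfig(seed=11)
    stack, truth = tq.generate_section_image(config, sample_id="s1")
    return config, stack, truth


@pytest.fixture(scope="session")
def section_cells(section):
    """The default section run through segmentation and cell extraction."""
    config, stack, truth = section
    mask = tq.segment_nuclei(stack)
    cells = tq.extract_cells(mask, stack)
    return config, stack, truth, mask, cells


def match_cells(cells, truth, pixel_size=1.0):
    """Match detected cells to ground-truth cells by nearest centroid.

    Returns (matched_pairs, recall, precision) where a match requires the
    detected centroid to fall within one nucleus radius of the true center.
    """
    import scipy.spatial

    det = cells[["x_um", "y_um"]].to_numpy()
    gt = truth[["x_um", "y_um"]].to_numpy()
    tree = scipy.spatial.cKDTree(gt)
    dist, idx = tree.query(det)
    matched = dist <= 4.0  # one default nucleus radius
    # each truth cell may be claimed once
    claimed = {}
    pairs = []
    for d_i, (ok, g_i, d) in enumerate(zip(matched, idx, dist)):
        if ok and (g_i not in claimed or d < claimed[g_i][1]):
            claimed[g_i] = (d_i, d)
    pairs = [(d_i, g_i) for g_i, (d_i, _) in claimed.items()]
    recall = len(pairs) / len(gt) if len(gt) else 1.0
    precision = len(pairs) / len(det) if len(det) else 1.0
    return pairs, recall, precision
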