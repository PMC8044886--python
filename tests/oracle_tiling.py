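"""Independently coded brute-force oracle for the dynamic-stride scan.

Simulates the cursor rules literally, window by window, with an occupancy
raster for the disjointness check (no integral image, no box arithmetic),
so it shares no code path with the production scanner.
"""

import numpy as np


def brute_force_scan(mask, patch_size, coverage_threshold, fine_stride_fraction):
    """Returns a list of (row0, col0, coverage) in acceptance order."""
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    fine = max(1, int(round(fine_stride_fraction * patch_size)))
    occupied = np.zeros((h, w), dtype=bool)
    accepted = []
    row = 0
    while row + patch_size <= h:
        row_had_accept = False
        col = 0
        while col + patch_size <= w:
            window = mask[row:row + patch_size, col:col + patch_size]
            coverage = window.sum() / (patch_size * patch_size)
            free = not occupied[row:row + patch_size, col:col + patch_size].any()
            if coverage >= coverage_threshold and free:
                accepted.append((row, col, float(coverage)))
                occupied[row:row + patch_size, col:col + patch_size] = True
                row_had_accept = True
                col += patch_size
            else:
                col += fine
        row += patch_size if row_had_accept else fine
    return accepted


def random_block_mask(gen, height, width, cell=20, fill=0.5):
    """Blocky random mask with spatial structure (not pixel salt)."""
    blocks = gen.random((height // cell + 1, width // cell + 1)) < fill
    return np.repeat(np.repeat(blocks, cell, axis=0), cell, axis=1)[:height, :width]
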