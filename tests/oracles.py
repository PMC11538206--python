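"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.ndimage and the package's own labeling so
they constitute a second, independent route to the same answers.
"""

from collections import deque

import numpy as np

# all 26 neighbor offsets (face, edge, corner)
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by BFS flood fill; labels follow the
    lexicographic order of each component's first foreground voxel."""
    offsets = _OFFSETS_26 if connectivity == 26 else _OFFSETS_6
    mask = np.asarray(mask) > 0
    shape = mask.shape
    labels = np.zeros(shape, dtype=np.int32)
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        q = deque([start])
        labels[start] = next_label
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = next_label
                    q.append((nx, ny, nz))
    return labels


def sphere_volume_cm3(radius_mm: float) -> float:
    """Analytic sphere volume in cm^3."""
    return 4.0 / 3.0 * np.pi * (radius_mm / 10.0) ** 3
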