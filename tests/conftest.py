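import numpy as np
import pytest

from lipidscape import ReferenceStructure


@pytest.fixture(scope="session")
def rod_reference():
    """A 25-marker rigid rod along x, the idealized helix backbone."""
    return ReferenceStructure(
        np.stack([np.linspace(-18.0, 18.0, 25), np.zeros(25)], axis=1)
    )


def rotate(points, theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.asarray(points) @ np.array([[c, -s], [s, c]]).T


def brute_force_angle(frame_xy, ref_xy, resolution=1e-4):
    """Independent oracle: grid search over rotation angles minimizing RMSD.

    Explicitly applies each candidate rotation matrix to the reference and
    measures summed squared distance; no closed form anywhere.
    """
    frame = np.asarray(frame_xy, dtype=float)
    frame = frame - frame.mean(axis=0)
    ref = np.asarray(ref_xy, dtype=float)
    angles = np.arange(-np.pi, np.pi, resolution)
    c, s = np.cos(angles), np.sin(angles)
    # rotated[k] = ref @ R(angles[k]).T, shape (K, N, 2)
    rx = np.outer(c, ref[:, 0]) - np.outer(s, ref[:, 1])
    ry = np.outer(s, ref[:, 0]) + np.outer(c, ref[:, 1])
    cost = ((rx - frame[:, 0]) ** 2 + (ry - frame[:, 1]) ** 2).sum(axis=1)
    return float(angles[np.argmin(cost)])
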