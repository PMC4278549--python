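"""Gradient-direction point sets.

A 45-direction electrostatic-repulsion point set (antipodally symmetric
energy, numerically optimized) serves as the base direction set for
multi-shell protocol construction; any reasonably uniform 45-vector set is
interchangeable here.
"""
from __future__ import annotations

import numpy as np

# 45 unit vectors, minimum inter-axis angle ~21 deg
_DIRS45 = (
    (0.336088694075020, 0.797247132302550, -0.501439328084972),
    (0.056831463949121, -0.308063411930268, 0.949666846286255),
    (-0.811480349159383, -0.168158480408226, -0.559662727359042),
    (-0.365961831002196, -0.241124224851136, 0.898849846436800),
    (0.078831698995537, -0.380869368608865, -0.921262225041796),
    (0.173693086682604, 0.585820544403366, -0.791609121595762),
    (0.114452224342556, -0.988948284987413, -0.094244246315069),
    (-0.050234927832929, -0.904583123064720, -0.423327090430200),
    (-0.703202819638952, 0.309563545745109, 0.640059532854205),
    (-0.394525105628407, 0.556566715139279, 0.731152126870986),
    (-0.956163596374381, 0.030242898518877, -0.291267135217117),
    (-0.696651806647494, -0.092346303628095, 0.711441087161129),
    (-0.366006695884889, -0.751545765687804, -0.548833363275375),
    (0.266569688736854, -0.928736044360069, 0.257662494269440),
    (0.575922582902181, -0.543624868766006, 0.610561365107900),
    (-0.829900809996237, -0.554171912654450, 0.064483616465725),
    (-0.128341538477078, 0.018260164046774, 0.991561907250537),
    (0.228222357125583, 0.086952874327125, 0.969718388685238),
    (0.785841686200580, -0.618265171780729, -0.014178208362622),
    (0.973074283943866, -0.230000568845574, -0.015039157484543),
    (-0.880669341564115, -0.390277781246554, -0.268523303074976),
    (0.238520424705574, -0.597412459039178, 0.765641143606478),
    (0.849317352425440, 0.324833033063172, -0.416105197636392),
    (0.520965268418904, 0.845783811122183, -0.115086636691040),
    (0.846703150014771, -0.423064877014976, 0.322660635329701),
    (-0.859753086031546, 0.402158337376031, 0.314790887317563),
    (0.643331532694043, 0.722155937075946, 0.254195479085479),
    (0.436928661634159, -0.248691318976087, 0.864433902914802),
    (0.917352639972850, -0.042973600945415, -0.395749167474332),
    (0.489335988836265, -0.867941834535776, -0.085013304207679),
    (-0.625332795652103, 0.662902679599889, 0.411726768696440),
    (0.635118854415656, 0.494747719875100, 0.593168386248066),
    (-0.306587271740250, 0.838885346798363, 0.449750619492469),
    (0.660902391596146, 0.644761709471073, -0.384044745807612),
    (0.593267887178057, -0.748368472424395, 0.296610592400982),
    (0.982620895681846, 0.175574763494425, -0.060246807328550),
    (0.307070288650591, 0.936790928294654, 0.167721777038293),
    (0.552483976895787, 0.473375599158650, -0.686059033461848),
    (-0.444759262624541, 0.178820783757472, 0.877617414142426),
    (0.750222678282323, -0.197491035703464, 0.631001762127232),
    (0.557423667015542, 0.139420824416484, 0.818437956823835),
    (0.011921900725337, -0.691259649025502, -0.722508107852248),
    (-0.141293529067502, -0.968546127592653, 0.204828067825013),
    (-0.308258632254096, -0.462507536988371, -0.831302227754614),
    (0.047341931098341, -0.835447284709735, 0.547527694305056)
)


def base_pointset(n: int = 45) -> np.ndarray:
    """Return the built-in electrostatic point set as an (n, 3) float array."""
    if n != 45:
        raise ValueError(f"only the 45-direction point set is built in, got n={n}")
    d = np.array(_DIRS45, dtype=float)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def uniform_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n orientations uniformly on the unit sphere."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix via quaternion sampling."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
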