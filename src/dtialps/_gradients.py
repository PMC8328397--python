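"""Fixed 30-direction gradient table.

Thirty approximately uniform unit vectors on the upper hemisphere (spherical
Fibonacci lattice, golden-angle azimuth), frozen as literals so every run
and every machine uses the identical scheme.  Any user-supplied direction
set can replace it through :class:`dtialps.phantom.GradientScheme`.
"""

import numpy as np

DIRECTIONS_30 = np.array(
    [
        (0.9998611015, 0.0000000000, 0.0166666667),
        (-0.7364465902, 0.6746454030, 0.0500000000),
        (0.0871216343, -0.9927060876, 0.0833333333),
        (0.6042839097, 0.7881813531, 0.1166666667),
        (-0.9735724337, -0.1722112552, 0.1500000000),
        (0.8294543234, -0.5276309452, 0.1833333333),
        (-0.2534375716, 0.9427751338, 0.2166666667),
        (-0.4462713077, -0.8592682468, 0.2500000000),
        (0.9008293111, 0.3289814196, 0.2833333333),
        (-0.8767758545, 0.3619203271, 0.3166666667),
        (0.3970376086, -0.8484463079, 0.3500000000),
        (0.2764215900, 0.8812755869, 0.3833333333),
        (-0.7865283338, -0.4558092463, 0.4166666667),
        (0.8721993548, -0.1917505814, 0.4500000000),
        (-0.5034892365, 0.7161616282, 0.4833333333),
        (-0.1100291352, -0.8490872423, 0.5166666667),
        (0.6386078140, 0.5382193418, 0.5500000000),
        (-0.8115392591, 0.0335596962, 0.5833333333),
        (0.5580077952, -0.5552922859, 0.6166666667),
        (-0.0351024599, 0.7591230581, 0.6500000000),
        (-0.4677859351, -0.5605638897, 0.6833333333),
        (0.6911875319, 0.0929983048, 0.7166666667),
        (-0.5429467553, 0.3777682106, 0.7500000000),
        (0.1364300303, -0.6064451630, 0.7833333333),
        (0.2869278839, 0.5007274158, 0.8166666667),
        (-0.5018620617, -0.1601076858, 0.8500000000),
        (0.4255228911, -0.1966023687, 0.8833333333),
        (-0.1542903257, 0.3686688455, 0.9166666667),
        (-0.1056816904, -0.2938220215, 0.9500000000),
        (0.1609379457, 0.0845844738, 0.9833333333),
    ],
    dtype=np.float64,
)
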