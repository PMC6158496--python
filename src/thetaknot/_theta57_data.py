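"""Synthetic stand-in diagram for the theta5_7 catalog entry.

This is NOT a transcription of the published curve table (which is not
reproducible here); it is a 5-crossing theta-curve found by a
deterministic search over single crossing changes applied to expanded
trivial-theta diagrams, so it has unknotting number one by construction.
Its Yamada fingerprint is distinct from every other catalog entry and
from all of their mirrors, and bounded simplification does not reduce it
below five crossings.  The positional name ``theta5_7`` is a label of
convenience only.
"""

from .diagram import PlanarDiagram, SISTER_A, SISTER_B, UNREPLICATED


def diagram() -> PlanarDiagram:
    return PlanarDiagram(
        crossings={0: 1, 1: 1, 2: 1, 3: 1, 4: 0},
        vertices={0, 1},
        arcs={
            0: (("v", 0, 0), ("x", 0, 0), UNREPLICATED),
            1: (("v", 0, 1), ("x", 1, 3), SISTER_A),
            2: (("v", 0, 2), ("x", 2, 1), SISTER_B),
            3: (("v", 1, 0), ("x", 3, 3), SISTER_B),
            4: (("v", 1, 1), ("x", 0, 2), UNREPLICATED),
            5: (("v", 1, 2), ("x", 4, 2), SISTER_A),
            6: (("x", 0, 1), ("x", 2, 0), SISTER_A),
            7: (("x", 0, 3), ("x", 3, 2), SISTER_A),
            8: (("x", 1, 0), ("x", 3, 1), SISTER_B),
            9: (("x", 1, 1), ("x", 3, 0), SISTER_A),
            10: (("x", 1, 2), ("x", 4, 1), SISTER_B),
            11: (("x", 2, 2), ("x", 4, 0), SISTER_A),
            12: (("x", 2, 3), ("x", 4, 3), SISTER_B),
        },
    )
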