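"""Treatment strategy labels for the eight-arm prophylaxis comparison.

The comparison covers standard of care (SoC) and every combination of
metoclopramide (Met), ceftriaxone (Cef) and paracetamol (Par) given on top
of it, forming a mutually exclusive, collectively exhaustive set of eight
options from the underlying 2x2x2 factorial design.
"""

from __future__ import annotations

#: Canonical strategy order used throughout the package (tables, arrays).
STRATEGIES: tuple[str, ...] = (
    "SoC",
    "Par",
    "Cef",
    "Cef-Par",
    "Met",
    "Met-Par",
    "Met-Cef",
    "Met-Cef-Par",
)

#: Drug components of each strategy.
COMPONENTS: dict[str, tuple[str, ...]] = {
    "SoC": (),
    "Par": ("Par",),
    "Cef": ("Cef",),
    "Cef-Par": ("Cef", "Par"),
    "Met": ("Met",),
    "Met-Par": ("Met", "Par"),
    "Met-Cef": ("Met", "Cef"),
    "Met-Cef-Par": ("Met", "Cef", "Par"),
}

N_STRATEGIES = len(STRATEGIES)

#: mRS health states 0..6; 6 is death (absorbing).
N_STATES = 7
DEATH = 6


def strategy_index(strategy: str) -> int:
    """Position of ``strategy`` in the canonical order.

    Raises
    ------
    KeyError
        If the label is not one of the eight strategies.
    """
    try:
        return STRATEGIES.index(strategy)
    except ValueError:
        raise KeyError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        ) from None
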