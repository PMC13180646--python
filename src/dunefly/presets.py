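"""Default behavioral vocabularies and composite-state presets.

The dancing dune fly (*Apotropina ornatipennis*) courtship ethogram comprises
18 discrete behaviors scored for males (M), females (F), or both (M/F).
Behaviors are not mutually exclusive — different body parts act at once — so
the sequence analysis operates on *composite states*: sets of simultaneously
expressed behaviors by one actor, labelled canonically as the alphabetically
sorted behavior set joined by "-" plus an actor tag, e.g.
``Face-off-Wing-sweep-(M)``.

Two state presets are provided:

* ``REDUCED_STATES`` — a 12-state vocabulary for fast simulation and testing;
* ``FULL_STATES`` — the 41-state vocabulary observed in the field study
  (which references two behaviors beyond the core ethogram, ``Copulation``
  and ``Wing-swing``, hence the extended vocabulary below).
"""

from __future__ import annotations

MALE = "M"
FEMALE = "F"
BOTH = "M/F"

#: The 18-behavior courtship ethogram: label -> sex applicability.
ETHOGRAM_BEHAVIORS: dict[str, str] = {
    "Chasing": MALE,
    "Face-off": MALE,
    "Foraging": BOTH,
    "Foreleg-touch": MALE,
    "Kick": FEMALE,
    "Orient": MALE,
    "Preening": BOTH,
    "Proboscis-touch": MALE,
    "Single-wing": BOTH,
    "Standing": FEMALE,
    "Straddle": MALE,
    "Turn": FEMALE,
    "Walking": FEMALE,
    "Wing-flap": BOTH,
    "Wing-flash": MALE,
    "Wing-sweep": MALE,
    "Wing-touch": MALE,
    "Wing-vibrate": MALE,
}

#: Extended vocabulary used by the full 41-state preset.  Two state labels in
#: the observed state list reference behaviors outside the core ethogram
#: (a single observed copulation, and the female "wing swing" display).
EXTENDED_BEHAVIORS: dict[str, str] = {
    **ETHOGRAM_BEHAVIORS,
    "Copulation": FEMALE,
    "Wing-swing": FEMALE,
}

BOUT_START = "Bout-start"
BOUT_END = "Bout-end"

# (actor, behaviors) pairs; labels are built canonically from these.
_FULL_STATE_DEFS: list[tuple[str, tuple[str, ...]]] = [
    (MALE, ("Chasing",)),
    (MALE, ("Chasing", "Wing-flap")),
    (FEMALE, ("Copulation",)),
    (MALE, ("Face-off",)),
    (MALE, ("Face-off", "Single-wing")),
    (MALE, ("Face-off", "Wing-flap")),
    (MALE, ("Face-off", "Wing-flash")),
    (MALE, ("Face-off", "Wing-sweep")),
    (MALE, ("Face-off", "Wing-touch")),
    (MALE, ("Face-off", "Wing-vibrate")),
    (FEMALE, ("Kick",)),
    (MALE, ("Orient",)),
    (MALE, ("Orient", "Single-wing")),
    (MALE, ("Orient", "Wing-flap")),
    (MALE, ("Orient", "Wing-flash")),
    (MALE, ("Orient", "Wing-sweep")),
    (MALE, ("Orient", "Wing-touch")),
    (MALE, ("Orient", "Wing-vibrate")),
    (MALE, ("Single-wing",)),
    (FEMALE, ("Single-wing", "Standing")),
    (FEMALE, ("Single-wing", "Turn")),
    (FEMALE, ("Single-wing", "Walking")),
    (FEMALE, ("Standing",)),
    (MALE, ("Straddle",)),
    (MALE, ("Single-wing", "Straddle")),
    (MALE, ("Straddle", "Wing-flap")),
    (MALE, ("Straddle", "Wing-flash")),
    (MALE, ("Straddle", "Wing-sweep")),
    (MALE, ("Straddle", "Wing-touch")),
    (MALE, ("Straddle", "Wing-vibrate")),
    (FEMALE, ("Turn",)),
    (FEMALE, ("Walking",)),
    (MALE, ("Wing-flap",)),
    (FEMALE, ("Standing", "Wing-flap")),
    (FEMALE, ("Turn", "Wing-flap")),
    (FEMALE, ("Walking", "Wing-flap")),
    (FEMALE, ("Standing", "Wing-swing")),
    (FEMALE, ("Walking", "Wing-swing")),
    (MALE, ("Wing-vibrate",)),
]

_REDUCED_STATE_DEFS: list[tuple[str, tuple[str, ...]]] = [
    (MALE, ("Orient",)),
    (MALE, ("Orient", "Wing-flash")),
    (MALE, ("Orient", "Wing-vibrate")),
    (MALE, ("Face-off",)),
    (MALE, ("Face-off", "Wing-sweep")),
    (MALE, ("Wing-flap",)),
    (MALE, ("Chasing",)),
    (FEMALE, ("Standing",)),
    (FEMALE, ("Walking",)),
    (FEMALE, ("Turn",)),
    (FEMALE, ("Kick",)),
    (FEMALE, ("Standing", "Wing-flap")),
]


def state_label(actor: str, behaviors) -> str:
    """Canonical composite-state label: sorted behaviors + actor tag."""
    return "-".join(sorted(behaviors)) + f"-({actor})"


def _build(defs):
    labels = [state_label(a, b) for a, b in defs]
    mapping = {state_label(a, b): (a, tuple(sorted(b))) for a, b in defs}
    return labels, mapping


#: 41 observed composite states (sequence analysis), canonical labels.
FULL_STATES, FULL_STATE_DECOMPOSITION = _build(_FULL_STATE_DEFS)
FULL_STATES = [BOUT_END, BOUT_START] + sorted(FULL_STATES)

#: 12-state reduced preset for fast tests and desk-scale simulation.
REDUCED_STATES, REDUCED_STATE_DECOMPOSITION = _build(_REDUCED_STATE_DEFS)
REDUCED_STATES = [BOUT_END, BOUT_START] + sorted(REDUCED_STATES)


def parse_state_label(label: str, vocabulary=None) -> tuple[str, tuple[str, ...]]:
    """Decompose a canonical composite-state label into (actor, behaviors).

    Greedy longest-prefix matching against the behavior vocabulary; works
    because no behavior label is a hyphen-boundary prefix of another.
    """
    vocabulary = vocabulary or EXTENDED_BEHAVIORS
    if label.endswith("-(M)"):
        actor, body = MALE, label[: -len("-(M)")]
    elif label.endswith("-(F)"):
        actor, body = FEMALE, label[: -len("-(F)")]
    else:
        raise ValueError(f"state label {label!r} lacks an actor tag")
    behaviors = []
    while body:
        matches = [
            b for b in vocabulary
            if body == b or body.startswith(b + "-")
        ]
        if not matches:
            raise ValueError(f"cannot decompose state label {label!r} at {body!r}")
        best = max(matches, key=len)
        behaviors.append(best)
        body = body[len(best) + 1:]
    return actor, tuple(behaviors)
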