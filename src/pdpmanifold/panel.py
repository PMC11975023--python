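"""Odor panels: stimulus identities, chemical classes and conditioning roles.

The standard juvenile panel has six odors in two correlated classes —
three amino-acid-like odors (class "A") and three bile-acid-like odors
(class "B").  In a discrimination experiment one amino acid is the rewarded
conditioned stimulus (CS+), one is the unrewarded CS−, and the third amino
acid (AA3) probes generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field


ROLES = ("CS+", "CS-", "AA3", "novel")


@dataclass(frozen=True)
class OdorPanel:
    """A labeled set of odors with class membership and optional conditioning roles.

    Parameters
    ----------
    odor_ids : tuple of str
        Unique odor labels, in presentation order.
    class_of : dict
        Map odor -> chemical class label ("A" amino-acid-like,
        "B" bile-acid-like).
    conditioning : dict
        Optional map odor -> role; at most one "CS+" and one "CS-".
    """

    odor_ids: tuple
    class_of: dict
    conditioning: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "odor_ids", tuple(self.odor_ids))
        if len(set(self.odor_ids)) != len(self.odor_ids):
            raise ValueError("odor ids must be unique")
        missing = [o for o in self.odor_ids if o not in self.class_of]
        if missing:
            raise ValueError(f"odors without a class: {missing}")
        for role in ("CS+", "CS-"):
            n = sum(1 for r in self.conditioning.values() if r == role)
            if n > 1:
                raise ValueError(f"at most one {role} allowed, got {n}")
        unknown = set(self.conditioning.values()) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown conditioning roles: {sorted(unknown)}")

    @property
    def n_odors(self) -> int:
        return len(self.odor_ids)

    def index(self, odor: str) -> int:
        return self.odor_ids.index(odor)

    def odors_of_class(self, cls: str) -> list:
        return [o for o in self.odor_ids if self.class_of[o] == cls]

    def odor_with_role(self, role: str):
        """Return the odor carrying ``role`` or None."""
        for o, r in self.conditioning.items():
            if r == role:
                return o
        return None

    @property
    def classes(self) -> list:
        seen = []
        for o in self.odor_ids:
            c = self.class_of[o]
            if c not in seen:
                seen.append(c)
        return seen


def panel_from_dict(data: dict) -> OdorPanel:
    """Build a panel from a config mapping (e.g. the ``panel:`` section of a
    YAML file) with keys ``odor_ids``, ``class_of`` and optional
    ``conditioning``."""
    return OdorPanel(
        tuple(data["odor_ids"]),
        dict(data["class_of"]),
        dict(data.get("conditioning", {})),
    )


def default_panel(conditioned: bool = True) -> OdorPanel:
    """Six odors, two classes of three (A1–A3 amino-acid-like, B1–B3 bile-acid-like).

    With ``conditioned=True``, A1 is the CS+, A2 the CS− and A3 the
    non-conditioned third amino acid.
    """
    ids = ("A1", "A2", "A3", "B1", "B2", "B3")
    class_of = {o: o[0] for o in ids}
    cond = {"A1": "CS+", "A2": "CS-", "A3": "AA3"} if conditioned else {}
    return OdorPanel(ids, class_of, cond)
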