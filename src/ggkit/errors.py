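"""Exception hierarchy shared across the toolkit.

Every error raised on a *user input* problem derives from :class:`GGError`;
programming errors stay as plain ``ValueError``/``TypeError``.
"""


class GGError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GGError):
    """A file could not be parsed under the named standard."""


class TopologyError(GGError):
    """Operation applied to the wrong topology (e.g. rotate on linear DNA)."""


class ConfigError(GGError):
    """Malformed enzyme/scheme configuration (e.g. cut index outside sequence)."""


class ValidationError(GGError):
    """Input violates a stated precondition."""


class MissingJunction(GGError):
    """No circular closure exists; carries the unmatched overhang labels."""

    def __init__(self, message, unmatched_labels=()):
        super().__init__(message)
        self.unmatched_labels = tuple(unmatched_labels)


class AmbiguousAssembly(GGError):
    """More than one stable circular closure; carries the colliding labels."""

    def __init__(self, message, colliding_labels=(), closures=()):
        super().__init__(message)
        self.colliding_labels = tuple(colliding_labels)
        self.closures = tuple(closures)


class SlotHeterogeneity(GGError):
    """Multiplex options within one slot expose different end labels."""


class UnassignablePart(GGError):
    """No slot span matches the part's insert end labels."""


class MultiInsertPart(GGError):
    """More than one released fragment matches a slot span."""


class SlotCoverage(GGError):
    """A construct selection does not tile the slot scheme exactly once."""

    def __init__(self, message, uncovered=(), overlapping=()):
        super().__init__(message)
        self.uncovered = tuple(uncovered)
        self.overlapping = tuple(overlapping)


class DomesticationRequired(GGError):
    """An insert still carries internal recognition sites."""

    def __init__(self, message, site_counts=None):
        super().__init__(message)
        self.site_counts = dict(site_counts or {})


class NoSilentLesion(GGError):
    """No synonymous substitution can remove a recognition site in frame."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class SynthesisRecommended(GGError):
    """Too many internal sites for PCR-based domestication to be practical."""


class AnnealError(GGError):
    """Two oligo strands do not anneal with perfect duplex complementarity."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position
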