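"""Typed exceptions shared across the pipeline stages."""


class GliascopeError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(GliascopeError):
    """An image or channel carries no usable contrast (single-valued)."""


class PlacementError(GliascopeError):
    """The synthetic generator could not place objects without overlap."""


class SpecError(GliascopeError):
    """A generator or analysis spec violates its invariants."""


class ConfigError(GliascopeError):
    """A configuration value is out of range (e.g. cutoff above Nyquist)."""


class NoBackgroundError(GliascopeError):
    """The cell mask covers the whole frame; no background pixels remain."""


class InvalidBackgroundError(GliascopeError):
    """Background fluorescence is non-positive; ΔF/F₀ is undefined."""


class DegenerateEventError(GliascopeError):
    """An event with zero extent (onset == offset) has no kinetics."""


class AxisMismatchError(GliascopeError):
    """An image file does not match the axis layout expected by a stage."""


class SchemaError(GliascopeError):
    """Records do not conform to the declared output schema."""
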