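"""Exception hierarchy shared across the pipeline stages."""


class FoilYieldError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FoilYieldError, ValueError):
    """A physical quantity violates its preconditions (e.g. t1/2 <= 0)."""


class DomainError(FoilYieldError, ValueError):
    """A value falls outside the validity range of a model or table."""


class SchemaError(FoilYieldError, ValueError):
    """A fixture or user file is malformed; the message names the field."""


class UnknownNuclideError(FoilYieldError, KeyError):
    """Lookup of a nuclide that is not in the registry."""


class RangedOutError(FoilYieldError, RuntimeError):
    """The proton beam stopped inside a foil during energy degradation."""

    def __init__(self, foil_name: str, layer_index: int | None = None):
        self.foil_name = foil_name
        self.layer_index = layer_index
        where = f"layer {layer_index} ({foil_name})" if layer_index is not None else foil_name
        super().__init__(f"beam ranged out inside {where}")
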