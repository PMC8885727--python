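"""Exception hierarchy shared across the pipeline."""


class SynapseCorrError(Exception):
    """Base class for all pipeline errors."""


class ContractError(SynapseCorrError, ValueError):
    """A call violated a precondition (bad argument, mismatched lengths...)."""


class FormatError(SynapseCorrError, ValueError):
    """An input file does not have the expected structure."""


class ParseError(FormatError):
    """A cell in a tabular input could not be parsed as a number."""


class PlacementError(SynapseCorrError, ValueError):
    """A requested geometry does not fit (overlapping boutons, ROI off-frame,
    too many synapses for the simulation box)."""


class DemixingError(SynapseCorrError, RuntimeError):
    """Spectral demixing failed (degenerate mixture, missing intensities)."""


class DriftEstimationError(SynapseCorrError, RuntimeError):
    """Drift cannot be estimated (too few frame bins)."""


class DegenerateGeometryError(SynapseCorrError, RuntimeError):
    """Point configuration has no valid tessellation or hull (coplanar,
    collinear or too few points)."""


class EmptyResultError(SynapseCorrError, RuntimeError):
    """An operation that requires a non-empty result produced none
    (e.g. rendering after a filter removed every localisation)."""
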