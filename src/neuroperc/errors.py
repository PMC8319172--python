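"""Exception hierarchy shared across the package."""


class NeuropercError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeuropercError):
    """Invalid configuration or generator specification."""


class DataError(NeuropercError):
    """Invalid input data (asymmetry, NaNs, out-of-range values, ...)."""


class FitError(NeuropercError):
    """A model fit failed or was requested on degenerate input."""


class DisconnectedGraphError(NeuropercError):
    """Operation requires a connected graph but the input is not.

    ``components`` holds the node sets of the connected components found.
    """

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class RankExhaustedError(NeuropercError):
    """The working graph disconnected before the requested spanning-tree rank.

    ``achieved_rank`` is the last rank for which a full spanning tree existed.
    """

    def __init__(self, message, achieved_rank):
        super().__init__(message)
        self.achieved_rank = achieved_rank
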