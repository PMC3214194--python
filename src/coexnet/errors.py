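"""Exception hierarchy shared by all coexnet modules."""


class CoexnetError(Exception):
    """Base class for all coexnet errors."""


class InvalidDataError(CoexnetError, ValueError):
    """Input data violates a contract (non-finite values, shape mismatch, ...)."""


class InvalidSpecError(CoexnetError, ValueError):
    """A parameter object is inconsistent with the data it is applied to."""


class NetworkFormatError(CoexnetError, ValueError):
    """A serialized network (GraphML, adjacency table, ...) is malformed."""


class UnknownNodeError(CoexnetError, KeyError):
    """A node id was requested that the (possibly filtered) network does not contain."""

    def __init__(self, node_id: str, detail: str = ""):
        self.node_id = node_id
        msg = f"unknown node id {node_id!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.args[0]


class InvalidArgumentError(CoexnetError, ValueError):
    """An operation argument is out of its admissible range."""
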