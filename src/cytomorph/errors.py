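"""Exception hierarchy for cytomorph."""


class CytomorphError(Exception):
    """Base class for all cytomorph errors."""


class MissingChannelError(CytomorphError):
    """A required cytometric channel is absent from an input file."""

    def __init__(self, channel: str, path=None):
        self.channel = channel
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"required channel {channel!r} not found{where}")


class TooFewEventsError(CytomorphError):
    """Fewer events survived gating than the configured minimum."""

    def __init__(self, sample_id, n_retained: int, minimum: int):
        self.sample_id = sample_id
        self.n_retained = n_retained
        self.minimum = minimum
        super().__init__(
            f"sample {sample_id!r}: {n_retained} events after gating "
            f"(minimum {minimum})"
        )


class DegenerateCloudError(CytomorphError):
    """The event cloud has no usable spread (e.g. all points identical)."""


class GateError(CytomorphError):
    """Invalid gate specification (degenerate or self-intersecting polygon)."""
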