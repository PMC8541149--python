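"""Exception types shared across the package.

``ValidationError`` maps to CLI exit code 2, ``InstabilityError`` to exit code 3.
"""


class ValidationError(ValueError):
    """Invalid anatomy, configuration, material or numerics input."""


class InstabilityError(RuntimeError):
    """The explicit time integration produced a non-finite field value."""

    def __init__(self, step: int, station_index: int, x_mm: float, field: str):
        self.step = step
        self.station_index = station_index
        self.x_mm = x_mm
        self.field = field
        super().__init__(
            f"non-finite value in field '{field}' at step {step}, "
            f"station {station_index} (x = {x_mm:.1f} mm); "
            "the time step is likely too large for the chosen coefficients"
        )
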