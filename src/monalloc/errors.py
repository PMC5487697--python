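"""Exception hierarchy shared across the toolkit.

All hard failures derive from :class:`MonallocError` so the CLI can map any
stage failure to a nonzero exit status with a stage-tagged message.
"""


class MonallocError(Exception):
    """Base class for all toolkit errors."""


class EmptyBandError(MonallocError):
    """No samples of the requested variable fall inside the depth band."""

    def __init__(self, station_id, day, variable, depth_min, depth_max):
        self.station_id = station_id
        self.day = day
        self.variable = variable
        super().__init__(
            f"empty band: no '{variable}' samples in [{depth_min}, {depth_max}] m "
            f"for station {station_id!r}, day {day}"
        )


class ProfileFitError(MonallocError):
    """Light-attenuation fit is impossible (too few points or nonpositive irradiance)."""


class SeriesError(MonallocError):
    """A station time series violates its invariants (ordering, emptiness)."""


class GridError(MonallocError):
    """Station-by-occasion grids are inconsistent or too sparse."""


class DesignError(MonallocError):
    """Cost/precision calculus received infeasible inputs (e.g. budget below fixed costs)."""


class ConfigError(MonallocError):
    """Run configuration failed validation."""


class ObservationError(MonallocError):
    """Observation table failed schema or key-uniqueness validation."""
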