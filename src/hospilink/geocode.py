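"""Pluggable geocoder interface (stub).

The linkage pipeline takes coordinates as input; converting street
addresses to coordinates is deliberately outside its scope because
networked geocoding services are neither reproducible nor redistributable.
Users with an address-only export can implement :class:`Geocoder` against
the service of their choice and pre-populate the lat/lon columns.
"""

from __future__ import annotations

from typing import Protocol

__all__ = ["Geocoder", "UnconfiguredGeocoder"]


class Geocoder(Protocol):
    def geocode(self, address: str) -> tuple[float, float]:
        """Return (lat, lon) in WGS84 decimal degrees for an address."""
        ...


class UnconfiguredGeocoder:
    """Placeholder that refuses to geocode; documents the extension point."""

    def geocode(self, address: str) -> tuple[float, float]:
        raise NotImplementedError(
            "no geocoder configured: provide coordinates in the cohort CSV "
            "or plug in a Geocoder implementation"
        )
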