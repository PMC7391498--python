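"""Exception types shared across the pipeline."""

from __future__ import annotations


class SeedstageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SeedstageError):
    """A config value is invalid or inconsistent."""


class GeometryError(SeedstageError):
    """A geometric operation cannot be performed (grid outside canvas,
    degenerate landmark quadrilateral, ...)."""


class LandmarksNotFound(SeedstageError):
    """Fewer than the required 5 landmark blobs survived filtering."""

    def __init__(self, n_found: int):
        self.n_found = n_found
        super().__init__(f"expected 5 landmarks, found {n_found}")


class RoleAssignmentAmbiguous(SeedstageError):
    """Corner-role assignment failed: two candidates share a quadrant."""


class OrientationUndefined(SeedstageError):
    """Fourier spectrum is too isotropic for a principal axis."""


class OntologyViolation(SeedstageError):
    """A label sequence regresses to an earlier stage; run post-processing
    (monotone clamping) before deriving event times."""
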