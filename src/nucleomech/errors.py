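"""Exception hierarchy for nucleomech."""


class NucleoMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(NucleoMechError):
    """Cell/nucleus geometry violates its invariants."""


class MeshingError(NucleoMechError):
    """Mesh generation produced a degenerate or empty mesh."""


class RoutingError(NucleoMechError):
    """A fiber class cannot be routed inside the given geometry."""


class TieError(NucleoMechError):
    """A fiber vertex has no mesh node within the tie tolerance."""


class SingularSystemError(NucleoMechError):
    """The constrained stiffness system is singular or ill-conditioned."""
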