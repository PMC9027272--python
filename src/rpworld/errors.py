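"""Exception types raised by the analytic and simulation modules."""


class RPWorldError(Exception):
    """Base class for all rpworld errors."""


class ParameterError(RPWorldError, ValueError):
    """A parameter is outside its admissible domain."""


class IneffectiveReplicationError(RPWorldError, ValueError):
    """m = 1: every replicase copy is a parasite, no self-replication."""


class DegenerateCoexistenceError(RPWorldError, ValueError):
    """m = 0 special case of the well-mixed equilibrium.

    With no miscopying, replicases and parasites can coexist in any
    proportion, but only on the knife edge aR*dP == aP*dR; otherwise no
    mixed equilibrium exists at all.

    Attributes
    ----------
    coexistence_possible : bool
        True iff aR*dP == aP*dR, in which case any ratio p/r is an
        equilibrium (p is undetermined).
    """

    def __init__(self, coexistence_possible: bool):
        self.coexistence_possible = coexistence_possible
        if coexistence_possible:
            msg = ("m = 0 with aR*dP == aP*dR: replicases and parasites "
                   "coexist in any proportion; no unique steady state")
        else:
            msg = ("m = 0 with aR*dP != aP*dR: no mixed equilibrium exists")
        super().__init__(msg)


class NoSteadyStateError(RPWorldError, ValueError):
    """The persistence inequality fails: no positive steady state."""


class NumericalInstabilityError(RPWorldError, RuntimeError):
    """Non-finite values appeared during integration (reduce dt)."""
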