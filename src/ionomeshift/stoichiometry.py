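"""Ratio-change calculus and the carbohydrate-dilution model.

If substance X rises by x% while substance Y falls by y%, the X:Y ratio
rises by ``(x + y) / (100 - y) * 100`` percent — the exact arithmetic, not
the x + y approximation, which matters at nutritionally relevant sizes
(C +6%, N -15% moves C:N by +24.7%, not +21%).  The same calculus drives
the "spoonful of sugars" dilution model: adding ``a`` grams of
non-structural carbohydrates (TNC) per 100 g of dry mass passively dilutes
every other component by ``a / (100 + a)`` while raising every TNC:X ratio
by exactly ``a / T`` (T = baseline TNC percent of dry mass).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RatioChangeInput",
    "DilutionSpec",
    "DilutionResult",
    "ratio_change",
    "dilute_with_tnc",
    "tnc_protein_vs_cn",
    "compensation_intake",
]


@dataclass(frozen=True)
class RatioChangeInput:
    """Signed percent changes of the numerator (x, up) and denominator
    (y, down) substances.

    Sign convention: ``x`` is the percent *increase* of the numerator and
    ``y`` the percent *decrease* of the denominator, both signed — pass
    x = -15 for a numerator that falls 15%, y = -10 for a denominator that
    rises 10%.
    """

    x: float
    y: float

    def __post_init__(self):
        if self.y >= 100:
            raise ValueError(
                f"y = {self.y} >= 100: the denominator cannot vanish")
        if 1 + self.x / 100.0 <= 0:
            raise ValueError(
                f"x = {self.x} <= -100: the numerator cannot lose 100%")


@dataclass(frozen=True)
class DilutionSpec:
    """Baseline TNC content T (percent of dry mass) and grams added per
    100 g dry mass."""

    baseline_tnc_pct: float
    added_g: float

    def __post_init__(self):
        if not 0 < self.baseline_tnc_pct < 100:
            raise ValueError("baseline TNC percent must be in (0, 100)")
        if self.added_g < 0:
            raise ValueError("added grams must be non-negative")


@dataclass(frozen=True)
class DilutionResult:
    """Concentration and ratio changes (%) from a TNC addition.

    Protein and minerals dilute identically — both are passive bystanders
    of the added carbohydrate mass — so their changes are always equal,
    and every TNC:X ratio change is the same ``a/T * 100``.
    """

    tnc_change_pct: float
    protein_change_pct: float
    minerals_change_pct: float
    tnc_to_protein_change_pct: float
    tnc_to_minerals_change_pct: float


def ratio_change(inp: RatioChangeInput | None = None, *,
                 x: float | None = None, y: float | None = None) -> float:
    """Percent change of the X:Y ratio when X rises x% and Y falls y%.

    ``(x + y) / (100 - y) * 100``, equivalently
    ``100 * ((1 + x/100) / (1 - y/100) - 1)``; the two forms agree to
    better than 12 significant digits and the first is returned.
    """
    if inp is None:
        inp = RatioChangeInput(x=float(x), y=float(y))
    return (inp.x + inp.y) / (100.0 - inp.y) * 100.0


def dilute_with_tnc(spec: DilutionSpec) -> DilutionResult:
    """Concentration/ratio shifts from adding TNC to 100 g of dry mass.

    With baseline TNC at T% and ``a`` g added per 100 g DM, total mass
    becomes 100 + a g while every non-TNC component keeps its grams:

    * non-TNC concentration change: ``-a / (100 + a) * 100`` %
    * TNC concentration change: ``a (100 - T) / (T (100 + a)) * 100`` %
    * TNC:X ratio change: ``a / T * 100`` % for every unchanged X.
    """
    T, a = spec.baseline_tnc_pct, spec.added_g
    other = -a / (100.0 + a) * 100.0
    tnc = a * (100.0 - T) / (T * (100.0 + a)) * 100.0
    ratio = a / T * 100.0
    return DilutionResult(
        tnc_change_pct=tnc,
        protein_change_pct=other,
        minerals_change_pct=other,
        tnc_to_protein_change_pct=ratio,
        tnc_to_minerals_change_pct=ratio,
    )


def tnc_protein_vs_cn(tnc_change_pct: float, protein_change_pct: float,
                      c_change_pct: float, n_change_pct: float
                      ) -> tuple[float, float]:
    """Side-by-side ratio shifts of the two plant-quality indicators.

    Returns ``(TNC:protein change %, C:N change %)``.  TNC:protein can move
    several-fold more than C:N because protein is more carbon-rich than
    carbohydrate, so a higher carbohydrate:protein barely registers in C.
    Changes are passed as signed percents of each component (declines
    negative).
    """
    tp = ratio_change(x=tnc_change_pct, y=-protein_change_pct)
    cn = ratio_change(x=c_change_pct, y=-n_change_pct)
    return tp, cn


def compensation_intake(dilution_pct: float) -> float:
    """Percent increase in intake compensating a nutrient dilution.

    A d% dilution needs ``100 * (1 / (1 - d/100) - 1)`` % more intake to
    restore the absolute nutrient amount (a 5% dilution needs 5.26% more,
    since 1.0526 * 0.95 ~= 1).
    """
    if not 0 <= dilution_pct < 100:
        raise ValueError("dilution percent must be in [0, 100)")
    return 100.0 * (1.0 / (1.0 - dilution_pct / 100.0) - 1.0)
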