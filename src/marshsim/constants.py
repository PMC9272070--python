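"""Model-wide calendar and lattice constants.

The simulation calendar uses a 364-day year (52 full calendar weeks) so
that weekly mowing schedules tile the year exactly.  Habitat cells are
250 m squares (6.25 ha); climate cells are 12 km squares.
"""

DAYS_PER_YEAR: int = 364
WEEKS_PER_YEAR: int = 52

SIZE_HAB: float = 250.0       # grassland (habitat) cell width, metres
SIZE_CLIM: float = 12_000.0   # climate cell width, metres

CELL_AREA_M2: float = SIZE_HAB * SIZE_HAB  # 62 500 m² per habitat cell

#: The three daily climate drivers, in storage order.
DRIVERS = ("temperature", "contact_water", "humidity")
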