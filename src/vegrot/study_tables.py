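"""Published seasonal water and nitrogen balances for the Dongbeiwang
open-field vegetable rotation experiment (Beijing, 2000-2001).

Two irrigation regimes (W1 conventional furrow, W2 optimised
micro-sprinkler) crossed with three fertiliser regimes (N1 conventional,
N2 budget-based optimum, N3 reduced optimum) were applied to a
cauliflower - amaranth - spinach rotation.  For each treatment-season the
study reports the water ledger (rainfall RF, irrigation I,
evapotranspiration ET, drainage D at 0.9 m, fresh yield Y, the WUE/IWUE
efficiencies and the storage residual Wbalance) and the nitrogen ledger
(manure Manu, fertiliser Fert, irrigation-borne N Nirr, net
mineralisation Nnet, crop uptake Nup, gaseous loss Ngas, nitrate
leaching Nlea, NUE and the residual Nbalance).

These rows serve two purposes: they are regression fixtures for the
ledger arithmetic in :mod:`vegrot.accounting`, and their seasonal
irrigation/fertiliser totals constrain the synthetic management
schedules in :mod:`vegrot.synthetic`.

Units: RF, I, ET, D, Wbalance in mm; Y in kg ha-1; WUE/IWUE in kg m-3;
all N masses in kg N ha-1; NUE in kg fresh yield per kg N.
"""

from __future__ import annotations

TREATMENTS = ("W1N1", "W1N2", "W1N3", "W2N1", "W2N2", "W2N3")
SEASONS = ("cauliflower", "amaranth", "spinach")
YEARS = (2000, 2001)

# Water ledger rows: (RF, I, ET, D, Y, WUE, IWUE, Wbalance)
# keyed by (year, treatment, season-or-"total").
WATER_ROWS: dict[tuple[int, str, str], tuple[float, ...]] = {
    (2000, "W1N1", "cauliflower"): (45.1, 294.1, 327.8, 20.4, 23400, 7.1, 8.0, -9.0),
    (2000, "W1N1", "amaranth"): (151.0, 85.5, 104.0, 111.5, 14300, 13.8, 16.7, 21.0),
    (2000, "W1N1", "spinach"): (65.6, 128.2, 130.2, 34.6, 34800, 26.7, 27.1, 29.0),
    (2000, "W1N1", "total"): (261.7, 507.8, 562.0, 166.5, 72500, 12.9, 14.3, 41.0),
    (2000, "W1N2", "cauliflower"): (45.1, 294.1, 323.1, 20.7, 19600, 6.1, 6.7, -4.6),
    (2000, "W1N2", "amaranth"): (151.0, 85.5, 99.4, 108.7, 13700, 13.8, 16.0, 28.4),
    (2000, "W1N2", "spinach"): (65.6, 128.2, 128.5, 37.1, 32900, 25.6, 25.7, 28.2),
    (2000, "W1N2", "total"): (261.7, 507.8, 551.0, 166.5, 66200, 12.0, 13.0, 52.0),
    (2000, "W1N3", "cauliflower"): (45.1, 294.1, 319.2, 19.5, 20500, 6.4, 7.0, 0.5),
    (2000, "W1N3", "amaranth"): (151.0, 85.5, 95.8, 108.6, 10800, 11.3, 12.6, 32.1),
    (2000, "W1N3", "spinach"): (65.6, 128.2, 127.7, 40.2, 36400, 28.5, 28.4, 25.9),
    (2000, "W1N3", "total"): (261.7, 507.8, 542.7, 168.3, 67700, 12.5, 13.3, 58.5),
    (2000, "W2N1", "cauliflower"): (45.1, 208.5, 281.2, 2.9, 21400, 7.6, 10.3, -30.5),
    (2000, "W2N1", "amaranth"): (151.0, 68.3, 100.9, 35.8, 13100, 13.0, 19.2, 82.6),
    (2000, "W2N1", "spinach"): (65.6, 89.3, 114.8, 4.0, 33100, 28.8, 37.1, 36.1),
    (2000, "W2N1", "total"): (261.7, 366.1, 496.9, 42.7, 67600, 13.6, 18.5, 88.2),
    (2000, "W2N2", "cauliflower"): (45.1, 208.5, 273.3, 1.2, 19700, 7.2, 9.4, -20.9),
    (2000, "W2N2", "amaranth"): (151.0, 68.3, 100.4, 38.0, 15200, 15.1, 22.3, 80.9),
    (2000, "W2N2", "spinach"): (65.6, 89.3, 115.3, 4.1, 32500, 28.2, 36.4, 35.5),
    (2000, "W2N2", "total"): (261.7, 366.1, 489.0, 43.3, 67400, 13.8, 18.4, 95.5),
    (2000, "W2N3", "cauliflower"): (45.1, 208.5, 284.8, 0.1, 18100, 6.4, 8.9, -31.3),
    (2000, "W2N3", "amaranth"): (151.0, 68.3, 101.1, 30.7, 16500, 16.3, 24.2, 87.5),
    (2000, "W2N3", "spinach"): (65.6, 89.3, 115.4, 6.8, 33900, 29.4, 38.0, 32.7),
    (2000, "W2N3", "total"): (261.7, 366.1, 501.3, 37.6, 68500, 13.7, 18.7, 88.9),
    (2001, "W1N1", "cauliflower"): (21.9, 290.7, 310.5, 30.5, 19200, 6.2, 6.6, -28.4),
    (2001, "W1N1", "amaranth"): (69.1, 107.4, 127.7, 0.0, 22500, 17.6, 20.9, 48.8),
    (2001, "W1N1", "spinach"): (52.7, 123.4, 121.3, 24.4, 30100, 24.8, 24.4, 30.4),
    (2001, "W1N1", "total"): (143.7, 521.5, 559.5, 54.9, 71800, 12.8, 13.8, 50.8),
    (2001, "W1N2", "cauliflower"): (21.9, 290.7, 304.3, 31.0, 16200, 5.3, 5.6, -22.7),
    (2001, "W1N2", "amaranth"): (69.1, 107.4, 129.6, 0.0, 18600, 14.4, 17.3, 46.9),
    (2001, "W1N2", "spinach"): (52.7, 123.4, 118.0, 16.8, 30200, 25.6, 24.5, 41.3),
    (2001, "W1N2", "total"): (143.7, 521.5, 551.9, 47.8, 65000, 11.8, 12.5, 65.5),
    (2001, "W1N3", "cauliflower"): (21.9, 290.7, 297.1, 29.5, 14500, 4.9, 5.0, -14.0),
    (2001, "W1N3", "amaranth"): (69.1, 107.4, 128.1, 0.0, 18300, 14.3, 17.0, 48.4),
    (2001, "W1N3", "spinach"): (52.7, 123.4, 118.0, 26.9, 31400, 26.6, 15.4, 31.2),
    (2001, "W1N3", "total"): (143.7, 521.5, 543.2, 56.4, 64200, 11.8, 12.3, 65.6),
    (2001, "W2N1", "cauliflower"): (21.9, 207.6, 258.0, 0.9, 19300, 7.5, 9.3, -29.4),
    (2001, "W2N1", "amaranth"): (69.1, 74.0, 112.7, 0.0, 22400, 19.9, 30.3, 30.4),
    (2001, "W2N1", "spinach"): (52.7, 84.6, 117.3, 0.4, 31600, 26.9, 37.4, 19.6),
    (2001, "W2N1", "total"): (143.7, 366.2, 488.0, 1.3, 73300, 15.0, 20.0, 20.6),
    (2001, "W2N2", "cauliflower"): (21.9, 207.6, 257.6, 0.2, 19000, 7.4, 9.2, -28.3),
    (2001, "W2N2", "amaranth"): (69.1, 74.0, 114.0, 0.0, 21200, 18.6, 28.6, 29.1),
    (2001, "W2N2", "spinach"): (52.7, 84.6, 118.9, 1.7, 25900, 21.8, 30.6, 16.7),
    (2001, "W2N2", "total"): (143.7, 366.2, 490.5, 1.9, 66100, 13.5, 18.1, 17.5),
    (2001, "W2N3", "cauliflower"): (21.9, 207.6, 254.9, 0.6, 18600, 7.3, 9.0, -26.0),
    (2001, "W2N3", "amaranth"): (69.1, 74.0, 113.7, 0.0, 15200, 13.4, 20.5, 29.4),
    (2001, "W2N3", "spinach"): (52.7, 84.6, 117.6, 9.5, 30400, 25.9, 35.9, 10.2),
    (2001, "W2N3", "total"): (143.7, 366.2, 486.2, 10.1, 64200, 13.2, 17.5, 13.6),
}

# Nitrogen ledger rows: (Manu, Fert, Nirr, Nnet, Nup, Ngas, Nlea, NUE, Nbalance)
N_ROWS: dict[tuple[int, str, str], tuple[float, ...]] = {
    (2000, "W1N1", "cauliflower"): (75, 450.0, 11.5, 25.0, 162.5, 141.3, 7.8, 75.1, 249.9),
    (2000, "W1N1", "amaranth"): (0, 100.0, 3.3, 23.5, 46.9, 24.9, 129.2, 71.1, -74.2),
    (2000, "W1N1", "spinach"): (0, 309.0, 5.0, 32.2, 120.0, 46.7, 58.7, 154.4, 120.8),
    (2000, "W1N1", "total"): (75, 859.0, 19.8, 80.7, 329.4, 212.9, 195.7, 98.2, 296.5),
    (2000, "W1N2", "cauliflower"): (75, 165.9, 11.5, 24.5, 158.6, 65.8, 6.9, 84.7, 45.6),
    (2000, "W1N2", "amaranth"): (0, 26.0, 3.3, 21.6, 44.1, 12.7, 79.0, 100.9, -84.9),
    (2000, "W1N2", "spinach"): (0, 81.4, 5.0, 32.5, 113.7, 16.1, 29.4, 206.7, -40.3),
    (2000, "W1N2", "total"): (75, 273.3, 19.8, 78.6, 316.4, 94.6, 115.3, 125.8, -79.6),
    (2000, "W1N3", "cauliflower"): (75, 189.8, 11.5, 24.6, 163.6, 79.2, 6.3, 82.3, 51.8),
    (2000, "W1N3", "amaranth"): (0, 26.2, 3.3, 21.4, 33.2, 14.6, 88.9, 79.0, -85.8),
    (2000, "W1N3", "spinach"): (0, 72.0, 5.0, 32.0, 117.7, 16.0, 32.4, 219.1, -57.1),
    (2000, "W1N3", "total"): (75, 288.0, 19.8, 78.0, 314.5, 109.8, 127.6, 122.7, -91.1),
    (2000, "W2N1", "cauliflower"): (75, 450.0, 8.1, 24.0, 159.8, 116.4, 0.8, 77.3, 280.1),
    (2000, "W2N1", "amaranth"): (0, 100.0, 2.7, 28.7, 44.9, 20.1, 22.0, 150.6, 44.4),
    (2000, "W2N1", "spinach"): (0, 309.0, 3.5, 32.7, 122.9, 38.5, 6.6, 197.0, 177.2),
    (2000, "W2N1", "total"): (75, 859.0, 14.3, 85.4, 327.6, 175.0, 29.4, 127.1, 501.7),
    (2000, "W2N2", "cauliflower"): (75, 83.6, 8.1, 24.1, 165.3, 32.0, 0.3, 99.7, -6.8),
    (2000, "W2N2", "amaranth"): (0, 25.7, 2.7, 28.3, 49.6, 15.2, 15.5, 189.3, -23.6),
    (2000, "W2N2", "spinach"): (0, 83.9, 3.5, 34.1, 118.3, 12.2, 3.3, 242.9, -12.3),
    (2000, "W2N2", "total"): (75, 193.2, 14.3, 86.5, 333.2, 59.4, 19.1, 163.7, -42.7),
    (2000, "W2N3", "cauliflower"): (75, 101.7, 8.1, 23.8, 164.7, 36.4, 0.0, 90.0, 7.5),
    (2000, "W2N3", "amaranth"): (0, 31.5, 2.7, 28.2, 57.1, 9.0, 8.2, 222.1, -11.9),
    (2000, "W2N3", "spinach"): (0, 55.4, 3.5, 32.7, 116.3, 8.1, 4.0, 264.0, -36.8),
    (2000, "W2N3", "total"): (75, 188.6, 14.3, 84.7, 338.1, 53.5, 12.2, 169.6, -41.2),
    (2001, "W1N1", "cauliflower"): (120, 450.0, 11.3, 32.8, 156.8, 113.3, 26.6, 64.7, 317.4),
    (2001, "W1N1", "amaranth"): (0, 100.0, 4.2, 33.9, 61.6, 16.0, 0.0, 289.9, 60.5),
    (2001, "W1N1", "spinach"): (0, 309.0, 4.8, 36.0, 104.2, 49.9, 30.4, 163.1, 165.3),
    (2001, "W1N1", "total"): (120, 859.0, 20.3, 102.7, 322.6, 179.2, 57.0, 128.5, 543.2),
    (2001, "W1N2", "cauliflower"): (120, 109.5, 11.3, 33.5, 135.8, 44.0, 13.8, 83.7, 80.7),
    (2001, "W1N2", "amaranth"): (0, 0.0, 4.2, 34.6, 55.6, 7.0, 0.0, 297.1, -23.8),
    (2001, "W1N2", "spinach"): (0, 126.3, 4.8, 35.0, 102.9, 22.9, 8.4, 225.0, 31.9),
    (2001, "W1N2", "total"): (120, 235.8, 20.3, 103.1, 294.3, 73.9, 22.2, 166.5, 88.8),
    (2001, "W1N3", "cauliflower"): (120, 71.6, 11.3, 29.4, 122.6, 34.4, 8.2, 87.8, 67.1),
    (2001, "W1N3", "amaranth"): (0, 0.0, 4.2, 34.0, 53.0, 8.5, 0.0, 297.6, -23.3),
    (2001, "W1N3", "spinach"): (0, 99.6, 4.8, 35.4, 102.5, 19.3, 15.2, 229.2, 2.8),
    (2001, "W1N3", "total"): (120, 171.2, 20.3, 98.8, 278.1, 62.2, 23.4, 176.5, 46.6),
    (2001, "W2N1", "cauliflower"): (120, 450.0, 8.1, 30.5, 156.6, 81.9, 1.1, 80.6, 369.0),
    (2001, "W2N1", "amaranth"): (0, 100.0, 2.9, 33.7, 62.4, 19.5, 0.0, 273.5, 54.7),
    (2001, "W2N1", "spinach"): (0, 309.0, 3.3, 34.0, 112.9, 32.1, 0.6, 217.0, 200.7),
    (2001, "W2N1", "total"): (120, 859.0, 14.3, 98.2, 331.9, 133.5, 1.7, 156.9, 624.4),
    (2001, "W2N2", "cauliflower"): (120, 62.0, 8.1, 30.5, 141.1, 22.2, 0.0, 116.4, 57.3),
    (2001, "W2N2", "amaranth"): (0, 0.0, 2.9, 33.2, 64.4, 3.2, 0.0, 313.6, -31.5),
    (2001, "W2N2", "spinach"): (0, 98.9, 3.3, 35.0, 108.1, 12.1, 0.5, 214.6, 16.5),
    (2001, "W2N2", "total"): (120, 160.9, 14.3, 98.7, 313.6, 37.5, 0.5, 188.0, 42.3),
    (2001, "W2N3", "cauliflower"): (120, 68.5, 8.1, 29.4, 139.8, 25.7, 0.2, 112.3, 60.3),
    (2001, "W2N3", "amaranth"): (0, 0.0, 2.9, 33.1, 51.8, 4.5, 0.0, 270.0, -20.3),
    (2001, "W2N3", "spinach"): (0, 71.8, 3.3, 34.5, 112.3, 10.6, 3.5, 240.5, -16.8),
    (2001, "W2N3", "total"): (120, 140.3, 14.3, 97.0, 303.9, 40.8, 3.7, 184.3, 23.2),
}

# Growing calendar (sowing date, harvest date) per year and crop.
CALENDAR: dict[tuple[int, str], tuple[str, str]] = {
    (2000, "cauliflower"): ("2000-04-03", "2000-06-06"),
    (2000, "amaranth"): ("2000-07-01", "2000-07-30"),
    (2000, "spinach"): ("2000-09-04", "2000-10-14"),
    (2001, "cauliflower"): ("2001-04-13", "2001-06-06"),
    (2001, "amaranth"): ("2001-06-24", "2001-07-22"),
    (2001, "spinach"): ("2001-09-06", "2001-10-29"),
}

# Soil profile, 0-120 cm in four horizons:
# (top cm, bottom cm, sand %, silt %, clay %, texture, bulk density g cm-3,
#  theta_fc, theta_wp, theta_s, pH)
SOIL_PROFILE: tuple[tuple, ...] = (
    (0, 30, 32.7, 50.2, 17.1, "Loam", 1.33, 0.33, 0.14, 0.50, 7.9),
    (30, 60, 16.4, 56.8, 26.8, "Silt loam", 1.52, 0.35, 0.15, 0.43, 7.9),
    (60, 90, 30.7, 47.6, 21.7, "Loam", 1.43, 0.35, 0.14, 0.44, 8.0),
    (90, 120, 35.0, 46.4, 18.6, "Loam", 1.62, 0.33, 0.14, 0.43, 8.0),
)

# Printed cells known to be internally inconsistent with the table's own
# component columns by more than plausible rounding; kept verbatim above,
# excluded from identity regression.  (year, treatment, season, column).
SUSPECT_CELLS: frozenset[tuple[int, str, str, str]] = frozenset({
    # Y/I = 31400/1234 = 25.4 kg m-3, printed 15.4: transposition typo.
    (2001, "W1N3", "spinach", "IWUE"),
    # Y/I = 18100/2085 = 8.68 kg m-3, printed 8.9; off by 0.22 even before
    # rounding Y to the nearest 100 kg ha-1.
    (2000, "W2N3", "cauliflower", "IWUE"),
})


def water_components(year: int, treatment: str, season: str) -> dict[str, float]:
    """Component columns (RF, I, ET, D, Y) of one water-ledger row."""
    rf, i, et, d, y, *_ = WATER_ROWS[(year, treatment, season)]
    return {"rainfall": rf, "irrigation": i, "et": et, "drainage": d, "yield_fresh": y}


def n_components(year: int, treatment: str, season: str) -> dict[str, float]:
    """Component columns of one nitrogen-ledger row (inputs and outputs)."""
    manu, fert, nirr, nnet, nup, ngas, nlea, *_ = N_ROWS[(year, treatment, season)]
    return {
        "manure_n": manu, "fertilizer_n": fert, "irrigation_n": nirr,
        "net_mineralization": nnet, "uptake_n": nup, "gaseous_n": ngas,
        "leached_n": nlea,
    }
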