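"""Published incidence tables from an Italian regional pediatric primary-care
AOM surveillance analysis (2010-2017), used as numerical reference values.

Each row: (stratum, year_or_group, events, person_years, ir, ci_low, ci_high)
with IR and CI printed as integers per 1000 person-years.
"""

ANNUAL_ROWS = [
    ("overall", 2010, 5510, 43692.02, 126, 123, 129),
    ("overall", 2011, 5871, 47609.77, 123, 120, 126),
    ("overall", 2012, 5895, 50643.46, 116, 113, 119),
    ("overall", 2013, 5694, 52192.36, 109, 106, 112),
    ("overall", 2014, 5195, 52805.74, 98, 96, 101),
    ("overall", 2015, 4783, 52392.12, 91, 89, 94),
    ("overall", 2016, 4658, 52184.01, 89, 87, 92),
    ("overall", 2017, 4077, 51348.38, 79, 77, 82),
    ("<2", 2010, 1504, 8396.77, 179, 170, 188),
    ("<2", 2011, 1500, 8687.03, 173, 164, 181),
    ("<2", 2012, 1483, 8475.04, 175, 166, 184),
    ("<2", 2013, 1383, 7757.59, 178, 169, 188),
    ("<2", 2014, 1259, 6746.95, 187, 176, 197),
    ("<2", 2015, 998, 5460.51, 183, 171, 194),
    ("<2", 2016, 953, 5192.16, 184, 172, 195),
    ("<2", 2017, 960, 5159.47, 186, 174, 198),
    ("2-4", 2010, 2625, 12338.81, 213, 205, 221),
    ("2-4", 2011, 2861, 12846.22, 223, 215, 231),
    ("2-4", 2012, 2816, 13289.06, 212, 204, 220),
    ("2-4", 2013, 2641, 13436.86, 197, 189, 204),
    ("2-4", 2014, 2503, 13207.40, 190, 182, 197),
    ("2-4", 2015, 2294, 12405.18, 185, 177, 192),
    ("2-4", 2016, 2189, 11145.09, 196, 188, 205),
    ("2-4", 2017, 1710, 9629.78, 178, 169, 186),
    ("5-14", 2010, 1381, 22956.44, 60, 57, 63),
    ("5-14", 2011, 1510, 26076.52, 58, 55, 61),
    ("5-14", 2012, 1596, 28879.35, 55, 53, 58),
    ("5-14", 2013, 1670, 30997.91, 54, 51, 56),
    ("5-14", 2014, 1433, 32851.39, 44, 41, 46),
    ("5-14", 2015, 1491, 34526.43, 43, 41, 45),
    ("5-14", 2016, 1516, 35846.76, 42, 40, 44),
    ("5-14", 2017, 1407, 36559.13, 38, 36, 40),
]

MEAN_ROWS = [
    ("overall", "mean", 41683, 402868.0, 103, 102, 104),
    ("sex", "M", 22245, 208832.96, 107, 105, 108),
    ("sex", "F", 19438, 194034.89, 100, 99, 102),
    ("age", "<2", 10040, 55875.52, 180, 176, 183),
    ("age", "2-4", 19639, 98298.40, 200, 197, 203),
    ("age", "5-14", 12004, 248693.93, 48, 47, 49),
]

ANNUAL_IR_SERIES = {
    band: [r[4] for r in ANNUAL_ROWS if r[0] == band]
    for band in ("overall", "<2", "2-4", "5-14")
}

MK_PUBLISHED_P = {"2-4": 0.0065, "<2": 0.0478}
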