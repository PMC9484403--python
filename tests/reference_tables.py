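"""Published reference values used as fixed inputs for aggregation checks.

``MANGROVE_SUMS`` holds reported total-suitability sums (region-wise sums
of cloglog values) for four Neotropical mangrove species — *Avicennia
germinans*, *Conocarpus erectus*, *Laguncularia racemosa*, *Rhizophora
mangle*, in that order — across three nested study regions and six time
windows.  ``MANGROVE_AVG`` and ``MANGROVE_GROUP_CHANGE`` are the reported
group averages and group percent changes versus the 2013-2018 present
window, which the aggregation functions must reproduce from the
per-species sums at 1-decimal precision.
"""

PRESENT = "2013-2018"

MANGROVE_SPECIES = ("avicennia", "conocarpus", "laguncularia", "rhizophora")

MANGROVE_SUMS = {
    ("NE Florida", "1984-1989"): (127.4, 24.9, 68.5, 40.5),
    ("NE Florida", "2001-2006"): (140.7, 28.8, 75.6, 42.3),
    ("NE Florida", "2013-2018"): (196.9, 41.7, 150.9, 87.9),
    ("NE Florida", "2021-2040"): (177.7, 33.6, 103.4, 70.0),
    ("NE Florida", "2041-2060"): (173.9, 34.5, 92.1, 67.5),
    ("NE Florida", "2061-2080"): (175.0, 28.4, 75.5, 63.8),
    ("Florida", "1984-1989"): (1141.8, 526.7, 1051.7, 740.9),
    ("Florida", "2001-2006"): (1299.4, 501.4, 1090.5, 825.9),
    ("Florida", "2013-2018"): (1502.3, 731.9, 1445.3, 1332.0),
    ("Florida", "2021-2040"): (1381.8, 687.7, 1227.0, 1086.3),
    ("Florida", "2041-2060"): (1363.6, 692.5, 1134.9, 1018.0),
    ("Florida", "2061-2080"): (1428.9, 633.2, 1145.8, 1032.4),
    ("Americas", "1984-1989"): (12928.4, 11707.3, 10947.2, 11172.9),
    ("Americas", "2001-2006"): (14242.3, 11144.4, 11518.6, 11021.2),
    ("Americas", "2013-2018"): (13878.3, 11047.5, 10674.8, 10949.7),
    ("Americas", "2021-2040"): (13566.9, 10914.5, 10227.8, 9740.8),
    ("Americas", "2041-2060"): (13882.7, 10401.4, 9304.6, 8713.3),
    ("Americas", "2061-2080"): (14395.7, 9821.3, 7948.7, 7987.3),
}

MANGROVE_AVG = {
    ("NE Florida", "1984-1989"): 65.3,
    ("NE Florida", "2001-2006"): 71.8,
    ("NE Florida", "2013-2018"): 119.4,
    ("NE Florida", "2021-2040"): 96.2,
    ("NE Florida", "2041-2060"): 92.0,
    ("NE Florida", "2061-2080"): 85.7,
    ("Florida", "1984-1989"): 865.3,
    ("Florida", "2001-2006"): 929.3,
    ("Florida", "2013-2018"): 1252.9,
    ("Florida", "2021-2040"): 1095.7,
    ("Florida", "2041-2060"): 1052.2,
    ("Florida", "2061-2080"): 1060.1,
    ("Americas", "1984-1989"): 11688.9,
    ("Americas", "2001-2006"): 11981.6,
    ("Americas", "2013-2018"): 11637.6,
    ("Americas", "2021-2040"): 11112.5,
    ("Americas", "2041-2060"): 10575.5,
    ("Americas", "2061-2080"): 10038.2,
}

MANGROVE_GROUP_CHANGE = {
    ("NE Florida", "1984-1989"): -45.3,
    ("NE Florida", "2001-2006"): -39.8,
    ("NE Florida", "2021-2040"): -19.4,
    ("NE Florida", "2041-2060"): -22.9,
    ("NE Florida", "2061-2080"): -28.2,
    ("Florida", "1984-1989"): -30.9,
    ("Florida", "2001-2006"): -25.8,
    ("Florida", "2021-2040"): -12.5,
    ("Florida", "2041-2060"): -16.0,
    ("Florida", "2061-2080"): -15.4,
    ("Americas", "1984-1989"): 0.4,
    ("Americas", "2001-2006"): 3.0,
    ("Americas", "2021-2040"): -4.5,
    ("Americas", "2041-2060"): -9.1,
    ("Americas", "2061-2080"): -13.7,
}

# species-level percent changes vs present (species, region, window) -> value
MANGROVE_SPECIES_CHANGE = {
    ("rhizophora", "NE Florida", "2061-2080"): -27.4,
    ("avicennia", "Americas", "2061-2080"): 3.7,
    ("avicennia", "NE Florida", "1984-1989"): -35.3,
    ("rhizophora", "Florida", "2001-2006"): -38.0,
}
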