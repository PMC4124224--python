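import numpy as np
import pytest

from ecovuln import AssessmentConfig, load_jilin_config, load_jilin_fixture

# Published reference tables for the western-Jilin case study, frozen at
# their printed 4-dp precision.  Row order: Tiaobei, Zhenlai, Tiaonan,
# Da'an, Tongyu, Qian'an, Fuyu, Changling, Qianguo.

JILIN_ZSCORES_4DP = """
0.8009 0.7247 -0.9611 1.0414 -0.3774 1.7407 1.6229 1.3161 -2.0220 1.2991
0.8009 0.7247 -1.1655 1.0850 0.1258 -0.1514 -0.6217 0.0013 1.4780 -0.6441
0.0700 -0.9692 0.2439 0.6193 1.1207 -0.8577 1.6554 0.7106 1.0907 -0.8833
1.3050 -0.9692 -1.5958 -0.3266 0.8348 -0.9334 0.4193 -0.1256 0.2720 -0.4680
0.9018 0.1255 1.5886 0.8376 1.4866 0.2018 -1.1747 0.3704 -0.8422 0.4861
-1.1398 1.6695 0.9001 0.2846 -0.3659 -1.0848 -0.9145 -0.5812 0.3978 0.3572
-1.5935 -0.9692 0.0502 -0.7924 0.1258 -0.9334 -0.6867 -2.1209 -0.7039 -1.8715
0.0196 -1.2342 0.8786 -2.1022 -1.7725 1.3370 -0.5566 -0.7023 0.3166 1.3842
-1.1650 0.8975 0.0610 -0.6468 -1.1779 0.6811 0.2566 1.1316 0.0130 0.3404
"""

JILIN_SHIFTED_4DP = """
3.0009 2.9247 1.2389 3.2414 1.8226 3.9407 3.8229 3.5161 0.1780 3.4991
3.0009 2.9247 1.0345 3.2850 2.3258 2.0486 1.5783 2.2013 3.6780 1.5559
2.2700 1.2308 2.4439 2.8193 3.3207 1.3423 3.8554 2.9106 3.2907 1.3167
3.5050 1.2308 0.6042 1.8734 3.0348 1.2666 2.6193 2.0744 2.4720 1.7320
3.1018 2.3255 3.7886 3.0376 3.6866 2.4018 1.0253 2.5704 1.3578 2.6861
1.0602 3.8695 3.1001 2.4846 1.8341 1.1152 1.2855 1.6188 2.5978 2.5572
0.6065 1.2308 2.2502 1.4076 2.3258 1.2666 1.5133 0.0791 1.4961 0.3285
2.2196 0.9658 3.0786 0.0978 0.4275 3.5370 1.6434 1.4977 2.5166 3.5842
1.0350 3.0975 2.2610 1.5532 1.0221 2.8811 2.4566 3.3316 2.2130 2.5404
"""

JILIN_PROPORTIONS_4DP = """
0.1516 0.1477 0.0626 0.1637 0.0921 0.1990 0.1931 0.1776 0.0090 0.1767
0.1516 0.1477 0.0522 0.1659 0.1175 0.1035 0.0797 0.1112 0.1858 0.0786
0.1146 0.0622 0.1234 0.1424 0.1677 0.0678 0.1947 0.1470 0.1662 0.0665
0.1770 0.0622 0.0305 0.0946 0.1533 0.0640 0.1323 0.1048 0.1249 0.0875
0.1567 0.1174 0.1913 0.1534 0.1862 0.1213 0.0518 0.1298 0.0686 0.1357
0.0535 0.1954 0.1566 0.1255 0.0926 0.0563 0.0649 0.0818 0.1312 0.1292
0.0306 0.0622 0.1136 0.0711 0.1175 0.0640 0.0764 0.0040 0.0756 0.0166
0.1121 0.0488 0.1555 0.0049 0.0216 0.1786 0.0830 0.0756 0.1271 0.1810
0.0523 0.1564 0.1142 0.0784 0.0516 0.1455 0.1241 0.1683 0.1118 0.1283
"""

JILIN_RANKING = [
    "Fuyu", "Changling", "Da'an", "Qian'an", "Qianguo",
    "Zhenlai", "Tiaonan", "Tongyu", "Tiaobei",
]


def _parse(table: str) -> np.ndarray:
    return np.array(
        [[float(v) for v in line.split()] for line in table.strip().splitlines()]
    )


@pytest.fixture(scope="session")
def jilin_matrix():
    return load_jilin_fixture()


@pytest.fixture(scope="session")
def jilin_config():
    return load_jilin_config()


@pytest.fixture(scope="session")
def default_config():
    return AssessmentConfig()


@pytest.fixture(scope="session")
def table_zscores():
    return _parse(JILIN_ZSCORES_4DP)


@pytest.fixture(scope="session")
def table_shifted():
    return _parse(JILIN_SHIFTED_4DP)


@pytest.fixture(scope="session")
def table_proportions():
    return _parse(JILIN_PROPORTIONS_4DP)
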