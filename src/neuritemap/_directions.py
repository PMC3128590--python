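"""Packaged 54-point gradient direction set (27 antipodal pairs).

Produced once by electrostatic-repulsion optimization on the sphere followed
by a polish that minimizes the worst-case quadrature error of even-degree
monomial averages through degree 4 (final worst-case relative error ~2.4e-8).
The 54 points are the 27 pairs below together with their antipodes.
"""

import numpy as np

_PAIRS27 = np.array([
    (9.48884183204364851e-01, 2.25754171502889150e-01, 2.20576202056408349e-01),
    (-9.80156984928633346e-01, -4.16130738255335031e-02, 1.93805668086363042e-01),
    (1.34108502190696838e-01, 9.58909380314649451e-01, 2.50015419493964219e-01),
    (8.54724787647438526e-03, -6.68337221370100404e-02, 9.97727516979987405e-01),
    (5.43920280482348639e-01, -6.37184333371973888e-01, 5.46028253651142714e-01),
    (-5.15880432327361471e-01, 5.36875947191387870e-01, 6.67556437216423659e-01),
    (-1.03139248902964817e-01, 7.83303095487618006e-01, 6.13024107140370145e-01),
    (-4.20750233999081735e-01, 8.69806524944888082e-01, 2.57693325006713991e-01),
    (6.58171884567018806e-01, -7.40617829560100804e-01, 1.35259014129131105e-01),
    (1.84937571964197689e-01, -9.65520903349987969e-01, 1.83214299851868573e-01),
    (6.28381270855696616e-01, 7.41843384331013933e-01, 2.34105471021262806e-01),
    (-4.71862214060677215e-02, 7.94549428668529734e-01, -6.05363251207017616e-01),
    (4.47615391553861791e-02, -4.07772854822224640e-01, -9.11985582935702865e-01),
    (3.36645008333709028e-01, 9.28709179779853788e-01, -1.55465101410664802e-01),
    (7.26718189757357691e-01, 3.23132757367360746e-01, -6.06189651670131502e-01),
    (-3.63769068799267958e-01, -6.55501006052646051e-01, -6.61808503759873434e-01),
    (-7.32102143331230470e-01, -3.59101274276659332e-01, -5.78854667894021624e-01),
    (-9.28800497496878763e-01, 2.97723874564241486e-01, -2.20658401979182239e-01),
    (-7.49776821551577322e-01, 1.64508561499102646e-01, -6.40914698737289124e-01),
    (2.47354124446665963e-01, 4.56461429275428099e-01, -8.54668883663759371e-01),
    (-8.01190672454969666e-01, 1.56812182567907993e-01, 5.77497572089652023e-01),
    (-4.66978533969634901e-01, -7.16911295414933702e-01, 5.17657457512255115e-01),
    (-4.52001614011104225e-01, 4.27078885974744027e-02, 8.90994151037425519e-01),
    (-8.33304126944066192e-01, 4.99462806840967555e-01, 2.36941209164911126e-01),
    (-3.14080519800580993e-01, 3.99231628015041862e-01, -8.61375373617249585e-01),
    (-4.31200418570662714e-01, -1.51740006388991100e-01, -8.89404952474155186e-01),
    (8.15898207550611931e-01, 5.55371748139252053e-01, -1.60848799449824276e-01)
])

DIRECTIONS54 = np.concatenate([_PAIRS27, -_PAIRS27])
DIRECTIONS54.setflags(write=False)
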