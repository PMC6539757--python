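fentanyl_template
     RDKit          3D

 54 56  0  0  0  0  0  0  0  0999 V2000
   -4.7470    3.0789   -2.2878 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6079    2.1344   -1.9329 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9682    1.1832   -0.7953 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0465    1.3146   -0.2152 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0075    0.1935   -0.4558 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.4163   -0.8624    0.4511 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5589   -1.4219    1.4098 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9781   -2.4674    2.2437 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2645   -2.9808    2.1312 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1325   -2.4471    1.1879 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.7111   -1.4020    0.3589 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5872    0.3208   -0.8657 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7712    1.2049    0.0880 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6450    1.4424   -0.4202 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2673    0.1877   -0.9959 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.7722    0.0998   -0.7633 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.1422   -0.2744    0.6753 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6352   -0.2112    0.8670 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.4377   -1.3218    0.5696 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.8234   -1.2502    0.7174 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.4189   -0.0715    1.1605 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.6303    1.0372    1.4593 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.2442    0.9703    1.3130 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5284   -1.0895   -0.6862 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8811   -0.9977   -1.2483 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6404    2.5220   -2.5891 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.4553    3.7317   -3.1163 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0155    3.7104   -1.4344 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7426    2.7364   -1.6395 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3620    1.5433   -2.8216 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5608   -1.0486    1.5790 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3047   -2.8721    2.9957 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.5955   -3.7861    2.7825 H   0  0  0  0  0  0  0  0  0  0  0  0
   -6.1439   -2.8364    1.0940 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.4234   -1.0324   -0.3762 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5902    0.8730   -1.8107 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2654    2.1744    0.2251 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7156    0.7694    1.0894 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6515    2.1803   -1.2302 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2792    1.8185    0.3881 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1994    0.2943   -2.0189 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.1860    1.0726   -1.0546 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.1482   -0.6468   -1.4732 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7970   -1.2875    0.9138 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.6558    0.3883    1.3999 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.9995   -2.2579    0.2302 H   0  0  0  0  0  0  0  0  0  0  0  0
    7.4431   -2.1161    0.4937 H   0  0  0  0  0  0  0  0  0  0  0  0
    8.4990   -0.0193    1.2806 H   0  0  0  0  0  0  0  0  0  0  0  0
    7.0997    1.9526    1.8135 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.6529    1.8488    1.5619 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5299   -1.2280    0.3991 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0771   -1.9121   -1.1567 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8278   -1.0513   -2.3450 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4423   -1.8913   -0.9612 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  3  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
 10 11  2  0
  5 12  1  0
 12 13  1  0
 13 14  1  0
 14 15  1  0
 15 16  1  0
 16 17  1  0
 17 18  1  0
 18 19  2  0
 19 20  1  0
 20 21  2  0
 21 22  1  0
 22 23  2  0
 15 24  1  0
 24 25  1  0
 11  6  1  0
 25 12  1  0
 23 18  1  0
  1 26  1  0
  1 27  1  0
  1 28  1  0
  2 29  1  0
  2 30  1  0
  7 31  1  0
  8 32  1  0
  9 33  1  0
 10 34  1  0
 11 35  1  0
 12 36  1  0
 13 37  1  0
 13 38  1  0
 14 39  1  0
 14 40  1  0
 15 41  1  0
 16 42  1  0
 16 43  1  0
 17 44  1  0
 17 45  1  0
 19 46  1  0
 20 47  1  0
 21 48  1  0
 22 49  1  0
 23 50  1  0
 24 51  1  0
 24 52  1  0
 25 53  1  0
 25 54  1  0
M  CHG  1  15   1
M  END
$$$$
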