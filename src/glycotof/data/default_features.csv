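name,H,N,F,E,L,Ge,Gl,Ac,mz,glycan_type,antennae,galactoses,sialic_total
H3N2,3,2,0,0,0,0,0,0,933.317,complex,0,0,0
H4N2,4,2,0,0,0,0,0,0,1095.3698,complex,0,0,0
H3N3,3,3,0,0,0,0,0,0,1136.3964,complex,1,0,0
H5N2,5,2,0,0,0,0,0,0,1257.4226,high_mannose,0,0,0
H3N3F1,3,3,1,0,0,0,0,0,1282.4543,complex,1,0,0
H4N3,4,3,0,0,0,0,0,0,1298.4492,complex,1,1,0
H3N4,3,4,0,0,0,0,0,0,1339.4757,complex,2,0,0
H6N2,6,2,0,0,0,0,0,0,1419.4755,high_mannose,0,0,0
H3N3Gl1,3,3,0,0,0,0,1,0,1425.4761,complex,1,0,1
H4N3F1,4,3,1,0,0,0,0,0,1444.5071,complex,1,1,0
H5N3,5,3,0,0,0,0,0,0,1460.502,hybrid,0,0,0
H3N3Ge1,3,3,0,0,0,1,0,0,1471.518,complex,1,0,1
H3N4F1,3,4,1,0,0,0,0,0,1485.5337,complex,2,0,0
H4N4,4,4,0,0,0,0,0,0,1501.5286,complex,2,1,0
H7N2,7,2,0,0,0,0,0,0,1581.5283,high_mannose,0,0,0
H4N3Gl1,4,3,0,0,0,0,1,0,1587.529,complex,1,1,1
H6N3,6,3,0,0,0,0,0,0,1622.5548,hybrid,0,0,0
H3N4Gl1,3,4,0,0,0,0,1,0,1628.5555,complex,2,0,1
H4N3Ge1,4,3,0,0,0,1,0,0,1633.5708,complex,1,1,1
H4N4F1,4,4,1,0,0,0,0,0,1647.5865,complex,2,1,0
H5N4,5,4,0,0,0,0,0,0,1663.5814,complex,2,2,0
H3N4Ge1,3,4,0,0,0,1,0,0,1674.5974,complex,2,0,1
H4N3F1Gl1,4,3,1,0,0,0,1,0,1733.5869,complex,1,1,1
H8N2,8,2,0,0,0,0,0,0,1743.5811,high_mannose,0,0,0
H5N3Gl1,5,3,0,0,0,0,1,0,1749.5818,hybrid,0,0,1
H4N3F1Ge1,4,3,1,0,0,1,0,0,1779.6287,complex,1,1,1
H4N4Gl1,4,4,0,0,0,0,1,0,1790.6083,complex,2,1,1
H5N3Ge1,5,3,0,0,0,1,0,0,1795.6237,hybrid,0,0,1
H5N4F1,5,4,1,0,0,0,0,0,1809.6393,complex,2,2,0
H4N4Ge1,4,4,0,0,0,1,0,0,1836.6502,complex,2,1,1
H5N5,5,5,0,0,0,0,0,0,1866.6608,complex,3,2,0
H4N3Gl2,4,3,0,0,0,0,2,0,1876.6087,complex,1,1,2
H9N2,9,2,0,0,0,0,0,0,1905.6339,high_mannose,0,0,0
H6N3Gl1,6,3,0,0,0,0,1,0,1911.6346,hybrid,0,0,1
H4N3Ge1Gl1,4,3,0,0,0,1,1,0,1922.6506,complex,1,1,2
H5N4L1,5,4,0,0,1,0,0,0,1936.6662,complex,2,2,1
H5N4Gl1,5,4,0,0,0,0,1,0,1952.6612,complex,2,2,1
H6N3Ge1,6,3,0,0,0,1,0,0,1957.6765,hybrid,0,0,1
H4N3Ge2,4,3,0,0,0,2,0,0,1968.6925,complex,1,1,2
H5N4E1,5,4,0,1,0,0,0,0,1982.7081,complex,2,2,1
H5N4Ge1,5,4,0,0,0,1,0,0,1998.703,complex,2,2,1
H5N5F1,5,5,1,0,0,0,0,0,2012.7187,complex,3,2,0
H6N5,6,5,0,0,0,0,0,0,2028.7136,complex,3,3,0
H4N4Gl2,4,4,0,0,0,0,2,0,2079.6881,complex,2,1,2
H4N4F2Gl1,4,4,2,0,0,0,1,0,2082.7242,complex,2,1,1
H5N4F1Gl1,5,4,1,0,0,0,1,0,2098.7191,complex,2,2,1
H4N4Ge1Gl1,4,4,0,0,0,1,1,0,2125.73,complex,2,1,2
H5N4F1Ge1,5,4,1,0,0,1,0,0,2144.7609,complex,2,2,1
H5N5Gl1,5,5,0,0,0,0,1,0,2155.7405,complex,3,2,1
H4N4Ge2,4,4,0,0,0,2,0,0,2171.7718,complex,2,1,2
H6N5F1,6,5,1,0,0,0,0,0,2174.7715,complex,3,3,0
H5N5Ge1,5,5,0,0,0,1,0,0,2201.7824,complex,3,2,1
H5N4Gl2,5,4,0,0,0,0,2,0,2241.7409,complex,2,2,2
H5N4F2E1,5,4,2,1,0,0,0,0,2274.8239,complex,2,2,1
H5N4Gl2Ac1,5,4,0,0,0,0,2,1,2283.7515,complex,2,2,2
H5N4Ge1Gl1,5,4,0,0,0,1,1,0,2287.7828,complex,2,2,2
H6N5Gl1,6,5,0,0,0,0,1,0,2317.7934,complex,3,3,1
H5N4Gl2Ac2,5,4,0,0,0,0,2,2,2325.7621,complex,2,2,2
H5N4Ge1Gl1Ac1,5,4,0,0,0,1,1,1,2329.7934,complex,2,2,2
H5N4Ge2,5,4,0,0,0,2,0,0,2333.8247,complex,2,2,2
H6N5Ge1,6,5,0,0,0,1,0,0,2363.8352,complex,3,3,1
H5N4Ge1Gl1Ac2,5,4,0,0,0,1,1,2,2371.8039,complex,2,2,2
H5N4Ge2Ac1,5,4,0,0,0,2,0,1,2375.8352,complex,2,2,2
H5N4F1Gl2,5,4,1,0,0,0,2,0,2387.7988,complex,2,2,2
H7N6,7,6,0,0,0,0,0,0,2393.8458,complex,4,4,0
H4N4Ge1Gl2,4,4,0,0,0,1,2,0,2414.8097,complex,2,1,3
H5N4Ge2Ac2,5,4,0,0,0,2,0,2,2417.8458,complex,2,2,2
H5N4F1Gl2Ac1,5,4,1,0,0,0,2,1,2429.8094,complex,2,2,2
H5N4F1Ge1Gl1,5,4,1,0,0,1,1,0,2433.8407,complex,2,2,2
H5N5Gl2,5,5,0,0,0,0,2,0,2444.8203,complex,3,2,2
H4N4Ge2Gl1,4,4,0,0,0,2,1,0,2460.8516,complex,2,1,3
H5N4F1Ge1Gl1Ac1,5,4,1,0,0,1,1,1,2475.8513,complex,2,2,2
H5N4F1Ge2,5,4,1,0,0,2,0,0,2479.8826,complex,2,2,2
H5N5Ge1Gl1,5,5,0,0,0,1,1,0,2490.8622,complex,3,2,2
H4N4Ge3,4,4,0,0,0,3,0,0,2506.8935,complex,2,1,3
H6N5F1Ge1,6,5,1,0,0,1,0,0,2509.8931,complex,3,3,1
H5N4F1Ge2Ac1,5,4,1,0,0,2,0,1,2521.8931,complex,2,2,2
H5N5Ge2,5,5,0,0,0,2,0,0,2536.904,complex,3,2,2
H5N4Ge1Gl2,5,4,0,0,0,1,2,0,2576.8626,complex,2,2,3
H6N5Gl2,6,5,0,0,0,0,2,0,2606.8731,complex,3,3,2
H5N4Ge2Gl1,5,4,0,0,0,2,1,0,2622.9044,complex,2,2,3
H6N5Ge1Gl1,6,5,0,0,0,1,1,0,2652.915,complex,3,3,2
H5N4Ge3,5,4,0,0,0,3,0,0,2668.9463,complex,2,2,3
H7N6Gl1,7,6,0,0,0,0,1,0,2682.9256,complex,4,4,1
H6N5Ge2,6,5,0,0,0,2,0,0,2698.9569,complex,3,3,2
H7N6Ge1,7,6,0,0,0,1,0,0,2728.9674,complex,4,4,1
H5N5Ge1Gl2,5,5,0,0,0,1,2,0,2779.9419,complex,3,2,3
H5N5Ge2Gl1,5,5,0,0,0,2,1,0,2825.9838,complex,3,2,3
H5N5Ge3,5,5,0,0,0,3,0,0,2872.0257,complex,3,2,3
H6N5Ge1Gl2,6,5,0,0,0,1,2,0,2941.9948,complex,3,3,3
H7N6Gl2,7,6,0,0,0,0,2,0,2972.0053,complex,4,4,2
H6N5Ge2Gl1,6,5,0,0,0,2,1,0,2988.0366,complex,3,3,3
H7N6Ge1Gl1,7,6,0,0,0,1,1,0,3018.0472,complex,4,4,2
H6N5Ge3,6,5,0,0,0,3,0,0,3034.0785,complex,3,3,3
H7N6Ge2,7,6,0,0,0,2,0,0,3064.089,complex,4,4,2
H6N5Ge2Gl2,6,5,0,0,0,2,2,0,3277.1164,complex,3,3,4
H7N6Ge1Gl2,7,6,0,0,0,1,2,0,3307.1269,complex,4,4,3
H6N5Ge3Gl1,6,5,0,0,0,3,1,0,3323.1582,complex,3,3,4
H7N6Ge2Gl1,7,6,0,0,0,2,1,0,3353.1688,complex,4,4,3
H6N5Ge4,6,5,0,0,0,4,0,0,3369.2001,complex,3,3,4
H7N6Ge3,7,6,0,0,0,3,0,0,3399.2107,complex,4,4,3
H7N6Ge2Gl2,7,6,0,0,0,2,2,0,3642.2486,complex,4,4,4
H7N6Ge3Gl1,7,6,0,0,0,3,1,0,3688.2904,complex,4,4,4
H7N6Ge4,7,6,0,0,0,4,0,0,3734.3323,complex,4,4,4
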