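{
 "ENDO": [
  -88.20191578205042,
  4.695175662081887,
  4.695202938213138,
  147.35727390772203,
  147.35727055194135,
  5.6485989567133584e-05,
  5.568900610070671e-05,
  0.9946887451785446,
  0.9946981725750909,
  0.0009091829013865505,
  0.8170106368785028,
  0.8170104555810086,
  0.00018124392526959826,
  0.5197508308160331,
  0.3210489855015744,
  0.0009876859487240493,
  0.9995695683452993,
  0.9995695586776268,
  0.0005032493369172381,
  0.9995695683563254,
  0.9995695599347683,
  2.2326544288731168e-09,
  0.999999991357129,
  0.9999999913516181,
  0.9999999913571304,
  0.9999999913566141,
  0.9999999913567529,
  0.0005382876732791023,
  0.9999999913570687,
  0.9999999913570721,
  7.780599758131974e-06,
  7.780759123766814e-06,
  0.00018852620245693357,
  0.000188519439586604,
  0.9967063524732033,
  1.499105690842583e-08,
  1.8738827248685658e-08,
  0.0002711275617605113
 ],
 "EPI": [
  -88.18624060233377,
  4.834829827127153,
  4.834856933374146,
  147.16736176517455,
  147.16735853255724,
  5.454519003893086e-05,
  5.375365699875949e-05,
  1.2496301638229217,
  1.2496284884334146,
  0.000912249305528915,
  0.8166790513107425,
  0.8166788421801466,
  0.0001817843409619923,
  0.519228127428521,
  0.3205924433936872,
  0.0009887301489100433,
  0.9995683858909432,
  0.9995683850625094,
  0.0005037816398635097,
  0.9995683858918883,
  0.999568385170039,
  2.240943369033385e-09,
  0.999999991320396,
  0.999999991314885,
  0.9999999913203973,
  0.999999991319881,
  0.9999999913200198,
  0.000469067069128806,
  0.9999999913203357,
  0.999999991320339,
  7.798586238540814e-06,
  7.798770164380137e-06,
  0.00018885831897001322,
  0.00018885052172724857,
  0.9967105385694149,
  9.431225460814283e-08,
  1.1789034312705624e-07,
  0.00025196049825830947
 ],
 "MID": [
  -88.13314975014582,
  5.242346775517545,
  5.242373713831235,
  146.835626672282,
  146.83562347239663,
  4.986614027748215e-05,
  4.9076026445638684e-05,
  0.8805904681632258,
  0.8805918429917803,
  0.0009227108516826497,
  0.8155522980921146,
  0.815552068515087,
  0.000183626692262746,
  0.5174578788509745,
  0.3190498169480632,
  0.0009922749865567823,
  0.9995643564475788,
  0.999564344178869,
  0.0005055886992761135,
  0.9995643564615112,
  0.9995643457684303,
  2.269246765968773e-09,
  0.9999999911948193,
  0.9999999911893084,
  0.9999999911948206,
  0.9999999911943044,
  0.9999999911944432,
  0.00032892919815661524,
  0.999999991194759,
  0.9999999911947623,
  7.859811598994455e-06,
  7.860013772694764e-06,
  0.0001899847037810222,
  0.00018997616658650746,
  0.9967246770227306,
  2.4968705353932712e-08,
  3.121088659992647e-08,
  0.0002087368356988365
 ]
}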