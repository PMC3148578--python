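"""Precomputed TW1 survival table (generated by scripts/build_tw1_table.py)."""

S_MIN = -10.0
S_STEP = 0.05
LOG_SF = [
    0, 0, 0, 0, 0,
    0, 0, 0, 0, 0,
    0, 0, 0, 0, 0,
    0, 0, 0, 0, 0,
    -1.11022302463e-16, -1.11022302463e-16, -2.22044604925e-16, -4.4408920985e-16, -6.66133814775e-16,
    -1.11022302463e-15, -1.99840144433e-15, -3.33066907388e-15, -5.55111512313e-15, -9.21485110439e-15,
    -1.53210777398e-14, -2.54241072639e-14, -4.16333634234e-14, -6.79456491071e-14, -1.10356168648e-13,
    -1.7807977315e-13, -2.86104473446e-13, -4.57078819238e-13, -7.26529947315e-13, -1.14874776358e-12,
    -1.80699899488e-12, -2.82773804372e-12, -4.40247838186e-12, -6.81932288418e-12, -1.05095931958e-11,
    -1.61155533364e-11, -2.45885534159e-11, -3.73304720476e-11, -5.63961100058e-11, -8.47820702568e-11,
    -1.26835320033e-10, -1.8883028476e-10, -2.79776979401e-10, -4.12547662783e-10, -6.0544069776e-10,
    -8.84336937404e-10, -1.28565935758e-09, -1.86041326962e-09, -2.67967182136e-09, -3.84198651409e-09,
    -5.48334290589e-09, -7.79047007719e-09, -1.10185369214e-08, -1.5514562866e-08, -2.17482250131e-08,
    -3.03521931088e-08, -4.21746647617e-08, -5.83474416929e-08, -8.03736941549e-08, -1.10240527788e-07,
    -1.50562628264e-07, -2.04764632564e-07, -2.77311489142e-07, -3.73997963481e-07, -5.02310627241e-07,
    -6.71878192528e-07, -8.95028914175e-07, -1.18747702888e-06, -1.56916382489e-06, -2.06528295905e-06,
    -2.70752404968e-06, -3.53557336066e-06, -4.59891552086e-06, -5.95898564318e-06, -7.69172685225e-06,
    -9.89061400445e-06, -1.26702101665e-05, -1.61703280742e-05, -2.05608741366e-05, -2.60474573987e-05,
    -3.28778499861e-05, -4.1349388691e-05, -5.18174092444e-05, -6.47048051682e-05, -8.05128016187e-05,
    -9.9833031031e-05, -0.000123360991354, -0.000151910958977, -0.000186432416849, -0.000228028043598,
    -0.000277973291557, -0.000337737560432, -0.000409006948924, -0.000493708539177, -0.000594036138531,
    -0.00071247737032, -0.000851841970614, -0.00101529111168, -0.00120636753604, -0.00142902624852,
    -0.00168766547779, -0.00198715758587, -0.00233287957324, -0.00273074280112, -0.00318722153142,
    -0.00370937986969, -0.00430489668814, -0.00498208810569, -0.00574992710913, -0.00661805991598,
    -0.00759681870414, -0.00869723036654, -0.00993102099014, -0.0113106158072, -0.0128491344216,
    -0.0145603811733, -0.0164588305693, -0.0185596077743, -0.0208784642266, -0.023431748508,
    -0.026236372666, -0.0293097742477, -0.0326698743624, -0.0363350321415, -0.0403239960104,
    -0.0446558522212, -0.0493499711261, -0.0544259516887, -0.0599035647419, -0.0658026955039,
    -0.0721432858553, -0.0789452768692, -0.0862285520611, -0.094012881802, -0.102317869303,
    -0.111162898544, -0.120567084474, -0.130549225785, -0.141127760487, -0.1523207245,
    -0.164145713424, -0.176619847584, -0.189759740448, -0.203581470443, -0.218100556173,
    -0.233331935011, -0.249289945009, -0.265988310029, -0.283440128005, -0.3016578622,
    -0.320653335318, -0.340437726324, -0.361021569798, -0.382414757671, -0.404626543151,
    -0.427665546682, -0.451539763744, -0.476256574341, -0.501822753984, -0.528244486032,
    -0.555527375206, -0.583676462142, -0.612696238831, -0.642590664809, -0.673363183968,
    -0.705016741869, -0.737553803444, -0.770976370976, -0.805286002277, -0.840483828956,
    -0.876570574707, -0.913546573548, -0.951411787934, -0.990165826691, -1.02980796272,
    -1.07033715043, -1.11175204282, -1.15405100824, -1.19723214675, -1.24129330608,
    -1.28623209711, -1.33204590894, -1.3787319235, -1.42628712964, -1.47470833675,
    -1.52399218791, -1.5741351725, -1.62513363835, -1.67698380342, -1.72968176686,
    -1.78322351979, -1.83760495538, -1.89282187863, -1.94887001561, -2.00574502221,
    -2.06344249254, -2.1219579668, -2.18128693884, -2.24142486316, -2.30236716165,
    -2.36410922992, -2.42664644315, -2.48997416176, -2.55408773656, -2.61898251372,
    -2.68465383928, -2.7510970635, -2.81830754475, -2.88628065332, -2.95501177476,
    -3.02449631309, -3.09472969374, -3.16570736626, -3.23742480675, -3.30987752019,
    -3.38306104246, -3.45697094223, -3.5316028227, -3.60695232306, -3.68301511993,
    -3.75978692852, -3.83726350378, -3.91544064126, -3.994314178, -4.0738799932,
    -4.15413400881, -4.23507219003, -4.31669054571, -4.39898512865, -4.48195203579,
    -4.56558740842, -4.6498874322, -4.73484833718, -4.82046639775, -4.90673793257,
    -4.99365930433, -5.08122691963, -5.16943722868, -5.25828672501, -5.34777194518,
    -5.43788946842, -5.52863591624, -5.620007952, -5.71200228054, -5.80461564768,
    -5.89784483978, -5.99168668323, -6.086138044, -6.18119582711, -6.27685697613,
    -6.37311847262, -6.46997733565, -6.56743062127, -6.66547542193, -6.76410886599,
    -6.86332811717, -6.96313037398, -7.06351286927, -7.16447286959, -7.26600767475,
    -7.36811461725, -7.47079106175, -7.57403440458, -7.67784207322, -7.78221152579,
    -7.88714025052, -7.99262576531, -8.09866561721, -8.20525738193, -8.31239866338,
    -8.42008709321, -8.52832033033, -8.63709606046, -8.74641199569, -8.85626587406,
    -8.96665545909, -9.07757853939, -9.18903292821, -9.30101646308, -9.41352700536,
    -9.52656243988, -9.64012067454, -9.75419963992, -9.86879728893, -9.98391159646,
    -10.099540559, -10.2156821941, -10.3323345406, -10.4494956576, -10.5671636245,
    -10.6853365407, -10.8040125251, -10.9231897158, -11.0428662702, -11.1630403641,
    -11.2837101917, -11.4048739654, -11.5265299153, -11.6486762893, -11.7713113524,
    -11.8944333864, -12.0180406902, -12.1421315789, -12.2667043842, -12.3917574534,
    -12.5172891499, -12.6432978522, -12.7697819546, -12.8967398662, -13.0241700108,
    -13.1520708271, -13.280440768, -13.4092783008, -13.5385819067, -13.6683500806,
    -13.7985813312, -13.9292741804, -14.0604271634, -14.1920388286, -14.3241077369,
    -14.4566324622, -14.5896115906, -14.7230437208, -14.8569274634, -14.9912614411,
    -15.1260442884, -15.2612746515, -15.3969511881, -15.5330725671, -15.6696374686,
    -15.8066445841, -15.9440926155, -16.0819802757, -16.2203062883, -16.3590693873,
    -16.4982683167, -16.6379018313, -16.7779686955, -16.9184676839, -17.0593975807,
    -17.20075718, -17.3425452853, -17.4847607095, -17.6274022752, -17.7704688137,
    -17.9139591657, -18.0578721808, -18.2022067175, -18.3469616429, -18.4921358331,
    -18.6377281724, -18.7837375537, -18.9301628782, -19.0770030553, -19.2242570027,
    -19.371923646, -19.5200019187, -19.6684907624, -19.8173891262, -19.9666959669,
    -20.1164102491, -20.2665309446, -20.4170570329, -20.5679875006, -20.7193213416,
    -20.8710575569, -21.0231951547, -21.1757331502, -21.3286705652, -21.4820064288,
    -21.6357397766, -21.7898696507, -21.9443951003, -22.0993151806, -22.2546289537,
    -22.4103354878, -22.5664338576, -22.7229231439, -22.8798024339, -23.0370708206,
    -23.1947274034, -23.3527712874, -23.5112015839, -23.6700174098, -23.829217888,
    -23.988802147, -24.1487693211, -24.3091185501, -24.4698489794, -24.63095976,
    -24.7924500483, -24.9543190061, -25.1165658005, -25.2791896039, -25.4421895941,
    -25.6055649538, -25.7693148712, -25.9334385393, -26.0979351563, -26.2628039255,
    -26.4280440549, -26.5936547578, -26.7596352522, -26.925984761, -27.0927025119,
    -27.2597877375, -27.4272396752, -27.5950575673, -27.7632406608, -27.9317882075,
    -28.100699464, -28.2699736918, -28.4396101574, -28.6096081321, -28.7799668923,
    -28.9506857196, -29.1217639008, -29.2932007282, -29.4649954999, -29.6371475197,
    -29.8096560978, -29.9825205511, -30.1557402037, -30.3293143872, -30.5032424418,
    -30.6775237173, -30.8521575735, -31.0271433821, -31.2024805279, -31.3781684109,
    -31.5542064484, -31.7305940775, -31.9073307589, -32.0844159805, -32.2618492619,
    -32.4396301608, -32.6177582792, -32.7962332723, -32.9750548583, -33.1542228305,
    -33.3337370722, -33.513597574, -33.6938044559, -33.8743579924, -34.055258644,
    -34.2365070955, -34.4181043009, -34.600051539, -34.7823504809, -34.9650032702,
    -35.1480126218,
]
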