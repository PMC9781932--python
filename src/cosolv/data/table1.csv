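solute,solvent1,solvent2,x2_star,temp,temp_unit,x,u_x,source
acetaminophen,DMSO,water,0.0,25,C,0.002000,0.000100,measured
acetaminophen,DMSO,water,0.0,30,C,0.002400,0.000100,measured
acetaminophen,DMSO,water,0.0,35,C,0.002800,0.000100,measured
acetaminophen,DMSO,water,0.0,40,C,0.003200,0.000100,measured
acetaminophen,DMSO,water,0.2,25,C,0.051700,0.000500,measured
acetaminophen,DMSO,water,0.2,30,C,0.072200,0.003800,measured
acetaminophen,DMSO,water,0.2,35,C,0.099800,0.001700,measured
acetaminophen,DMSO,water,0.2,40,C,0.136600,0.005100,measured
acetaminophen,DMSO,water,0.4,25,C,0.136500,0.003700,measured
acetaminophen,DMSO,water,0.4,30,C,0.183700,0.002100,measured
acetaminophen,DMSO,water,0.4,35,C,0.237900,0.009200,measured
acetaminophen,DMSO,water,0.4,40,C,0.314700,0.011500,measured
acetaminophen,DMSO,water,0.6,25,C,0.264700,0.008900,measured
acetaminophen,DMSO,water,0.6,30,C,0.316900,0.009900,measured
acetaminophen,DMSO,water,0.6,35,C,0.379500,0.006700,measured
acetaminophen,DMSO,water,0.6,40,C,0.452300,0.007900,measured
acetaminophen,DMSO,water,0.8,25,C,0.316100,0.009500,measured
acetaminophen,DMSO,water,0.8,30,C,0.370300,0.009600,measured
acetaminophen,DMSO,water,0.8,35,C,0.433800,0.005400,measured
acetaminophen,DMSO,water,0.8,40,C,0.510800,0.007800,measured
acetaminophen,DMSO,,1.0,25,C,0.303000,0.005500,measured
acetaminophen,DMSO,,1.0,30,C,0.357600,0.007100,measured
acetaminophen,DMSO,,1.0,35,C,0.422200,0.010200,measured
acetaminophen,DMSO,,1.0,40,C,0.489200,0.006200,measured
acetaminophen,DMF,water,0.2,25,C,0.059900,0.003500,measured
acetaminophen,DMF,water,0.2,30,C,0.076500,0.002600,measured
acetaminophen,DMF,water,0.2,35,C,0.094300,0.004000,measured
acetaminophen,DMF,water,0.2,40,C,0.118100,0.006500,measured
acetaminophen,DMF,water,0.4,25,C,0.161300,0.003900,measured
acetaminophen,DMF,water,0.4,30,C,0.193800,0.004600,measured
acetaminophen,DMF,water,0.4,35,C,0.236000,0.011800,measured
acetaminophen,DMF,water,0.4,40,C,0.288800,0.004400,measured
acetaminophen,DMF,water,0.6,25,C,0.310700,0.002800,measured
acetaminophen,DMF,water,0.6,30,C,0.345700,0.011900,measured
acetaminophen,DMF,water,0.6,35,C,0.390400,0.007400,measured
acetaminophen,DMF,water,0.6,40,C,0.446200,0.016000,measured
acetaminophen,DMF,water,0.8,25,C,0.352600,0.009000,measured
acetaminophen,DMF,water,0.8,30,C,0.385800,0.005500,measured
acetaminophen,DMF,water,0.8,35,C,0.431500,0.011900,measured
acetaminophen,DMF,water,0.8,40,C,0.493100,0.014000,measured
acetaminophen,DMF,,1.0,25,C,0.286900,0.006000,measured
acetaminophen,DMF,,1.0,30,C,0.318500,0.005600,measured
acetaminophen,DMF,,1.0,35,C,0.361400,0.006800,measured
acetaminophen,DMF,,1.0,40,C,0.427300,0.004600,measured
acetaminophen,4FM,water,0.2,25,C,0.051800,0.003400,measured
acetaminophen,4FM,water,0.2,30,C,0.071000,0.003800,measured
acetaminophen,4FM,water,0.2,35,C,0.095600,0.002600,measured
acetaminophen,4FM,water,0.2,40,C,0.125400,0.007100,measured
acetaminophen,4FM,water,0.4,25,C,0.096300,0.001900,measured
acetaminophen,4FM,water,0.4,30,C,0.130700,0.004300,measured
acetaminophen,4FM,water,0.4,35,C,0.166800,0.005000,measured
acetaminophen,4FM,water,0.4,40,C,0.204800,0.004700,measured
acetaminophen,4FM,water,0.6,25,C,0.129700,0.005000,measured
acetaminophen,4FM,water,0.6,30,C,0.168900,0.002800,measured
acetaminophen,4FM,water,0.6,35,C,0.215800,0.008200,measured
acetaminophen,4FM,water,0.6,40,C,0.261600,0.008500,measured
acetaminophen,4FM,water,0.8,25,C,0.154100,0.004600,measured
acetaminophen,4FM,water,0.8,30,C,0.194600,0.005500,measured
acetaminophen,4FM,water,0.8,35,C,0.244500,0.008400,measured
acetaminophen,4FM,water,0.8,40,C,0.295400,0.002200,measured
acetaminophen,4FM,,1.0,25,C,0.167300,0.005500,measured
acetaminophen,4FM,,1.0,30,C,0.208000,0.007300,measured
acetaminophen,4FM,,1.0,35,C,0.258900,0.002700,measured
acetaminophen,4FM,,1.0,40,C,0.311100,0.007300,measured
phenacetin,4FM,water,0.2,25,C,0.005900,0.000300,measured
phenacetin,4FM,water,0.2,30,C,0.007900,0.000200,measured
phenacetin,4FM,water,0.2,35,C,0.010800,0.000500,measured
phenacetin,4FM,water,0.2,40,C,0.015400,0.000400,measured
phenacetin,4FM,water,0.4,25,C,0.025300,0.000100,measured
phenacetin,4FM,water,0.4,30,C,0.030200,0.001400,measured
phenacetin,4FM,water,0.4,35,C,0.036400,0.001900,measured
phenacetin,4FM,water,0.4,40,C,0.046700,0.001600,measured
phenacetin,4FM,water,0.6,25,C,0.041900,0.000900,measured
phenacetin,4FM,water,0.6,30,C,0.048000,0.000100,measured
phenacetin,4FM,water,0.6,35,C,0.057800,0.002200,measured
phenacetin,4FM,water,0.6,40,C,0.071100,0.003200,measured
phenacetin,4FM,water,0.8,25,C,0.053300,0.000700,measured
phenacetin,4FM,water,0.8,30,C,0.060300,0.001500,measured
phenacetin,4FM,water,0.8,35,C,0.069400,0.001700,measured
phenacetin,4FM,water,0.8,40,C,0.082000,0.000700,measured
phenacetin,4FM,,1.0,25,C,0.061900,0.001800,measured
phenacetin,4FM,,1.0,30,C,0.068900,0.001400,measured
phenacetin,4FM,,1.0,35,C,0.079000,0.001300,measured
phenacetin,4FM,,1.0,40,C,0.091200,0.002100,measured
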