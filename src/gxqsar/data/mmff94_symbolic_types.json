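{
  "1": "CR",
  "2": "C=C",
  "3": "C=O",
  "4": "CSP",
  "5": "HC",
  "6": "OR",
  "7": "O=C",
  "8": "NR",
  "9": "N=C",
  "10": "NC=O",
  "11": "F",
  "12": "CL",
  "13": "BR",
  "14": "I",
  "15": "S",
  "16": "S=C",
  "17": "S=O",
  "18": "SO2",
  "19": "SI",
  "20": "CR4R",
  "21": "HOR",
  "22": "CR3R",
  "23": "HNR",
  "24": "HOCO",
  "25": "PO4",
  "26": "P",
  "27": "HN=C",
  "28": "HNCO",
  "29": "HOCC",
  "30": "CE4R",
  "31": "HOH",
  "32": "O2CM",
  "33": "HOS",
  "34": "NR+",
  "35": "OM",
  "36": "HNR+",
  "37": "CB",
  "38": "NPYD",
  "39": "NPYL",
  "40": "NC=C",
  "41": "CO2M",
  "42": "NSP",
  "43": "NSO2",
  "44": "STHI",
  "45": "NO2",
  "46": "N=O",
  "47": "NAZT",
  "48": "NSO",
  "49": "O+",
  "50": "HO+",
  "51": "O=+",
  "52": "HO=+",
  "53": "=N=",
  "54": "N+=C",
  "55": "NCN+",
  "56": "NGD+",
  "57": "CGD+",
  "58": "NPD+",
  "59": "OFUR",
  "60": "C%",
  "61": "NR%",
  "62": "NM",
  "63": "C5A",
  "64": "C5B",
  "65": "N5A",
  "66": "N5B",
  "67": "N2OX",
  "68": "N3OX",
  "69": "NPOX",
  "70": "OH2",
  "71": "HS",
  "72": "SM",
  "73": "SO2M",
  "74": "=S=O",
  "75": "-P=C",
  "76": "N5M",
  "77": "CLO4",
  "78": "C5",
  "79": "N5",
  "80": "CIM+",
  "81": "NIM+",
  "82": "N5OX"
}
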