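<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="boolstr">
    <xs:restriction base="xs:string">
      <xs:enumeration value="true"/>
      <xs:enumeration value="false"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="dwiqc_report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="summary">
          <xs:complexType>
            <xs:attribute name="scan_rejected" type="boolstr" use="required"/>
            <xs:attribute name="retained_fraction" type="xs:decimal" use="required"/>
            <xs:attribute name="incomplete" type="boolstr" use="required"/>
            <xs:attribute name="reject_reason" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="checks">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="check" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="passed" type="boolstr" use="required"/>
                  <xs:attribute name="detail" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="volumes">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="volume" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="index" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="retained" type="boolstr" use="required"/>
                  <xs:attribute name="stage" type="xs:string"/>
                  <xs:attribute name="reason" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="slice_correlations" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="volume" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="index" type="xs:nonNegativeInteger" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="interlace_correlations" type="xs:string" minOccurs="0"/>
        <xs:element name="directional" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="removed" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="volume" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="entropy" type="xs:decimal" use="required"/>
            <xs:attribute name="z" type="xs:decimal" use="required"/>
            <xs:attribute name="category" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="acceptable"/>
                  <xs:enumeration value="suspicious"/>
                  <xs:enumeration value="unacceptable"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="scan_rejected" type="boolstr" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="warnings" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="warning" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
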